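# rcdna

A random-code (RC) DNA data-storage codec. Files are split into K
fixed-width chunks, combined into K+m XOR "droplets" by a seeded random
GF(2) generator matrix selected for maximal decoding success, balanced
against biological constraints by iterative XOR with seeded random base
masks ("random equilibrium"), and assembled into fixed-layout 700-nt
strands:

```
adapter_fwd | times | payload | eq_counter | re_eq | check | adapter_rev
    20 nt     6 nt    639 nt     10 nt       2 nt    3 nt      20 nt
```

The 20-nt forward adapter doubles as the PRNG seed; the Times field records
which generator-matrix draw was accepted (and the droplet's row); the check
field XOR-folds the inner fields in 3-nt words so corrupted strands are
rejected before solving. Decoding finds the adapters, screens by length
(indel detection) and checksum, regenerates the generator matrix from
(seed, Times), and solves the augmented system by Gaussian XOR elimination.

The package also includes an error-channel simulator (substitution /
insertion / deletion / strand loss) and a classical LT-code baseline
(ideal and robust soliton distributions with belief-propagation peeling)
for recovery-rate comparisons at equal redundancy.

## Layout

| module | contents |
|---|---|
| `rcdna.gf2_engine` | splitmix64-style seeded PRNG, random bit matrices, Gaussian XOR elimination, generator-matrix selection, augmented-system solver |
| `rcdna.bioconstraints` | GC / homopolymer / micro-satellite detectors, constraint policy, Feller run-probability model, degree-distribution density |
| `rcdna.rc_codec` | segmentation, droplets, random equilibrium, strand assembly/parsing, encode/decode, density accounting |
| `rcdna.channel_sim` | error channel, soliton distributions, LT encode/decode, recovery experiments |
| `rcdna.io_cli` | `rc` command line, FASTA + JSON manifest I/O, fixture generation, stats |

## CLI

```sh
rc fixture --preset paper --seed 1 -o doc.bin       # 29,390-bit test file
rc encode doc.bin --bits 29390 -o doc               # doc.fasta + doc.manifest.json
rc decode doc.fasta doc.manifest.json -o restored.bin
rc simulate --seed 1 --k 8 --m 2 --levels 0.0,0.1 -o recovery.csv
rc stats --seed-count 72000                         # densities, Q(4,700), seed space
```

Encoding the 29,390-bit document produces 25 strands of 700 nt (K=23, m=2)
at 1.78 bits/nt excluding primers (1.68 including). Strand libraries travel
as single-line FASTA plus a JSON manifest holding everything the decoder
needs (adapters, K, m, layout, policy, row capacity, bit length, checksum);
decoding is order-independent and tolerates strand loss up to the rank
margin of the generator.

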