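"""Error-channel simulation and the LT-code baseline.

The channel applies per-strand loss followed by independent per-base edits
(deletion, substitution, insertion).  The LT baseline implements the
classical ideal/robust soliton degree distributions with belief-propagation
peeling, and ``recovery_experiment`` sweeps error grids for either codec,
emitting a tidy table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import BASES
from .errors import ConfigError, DomainError
from .rc_codec import EncodeResult, decode


@dataclass
class ChannelConfig:
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    loss_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("sub_rate", "ins_rate", "del_rate", "loss_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


def apply_channel(strands: list[str], config: ChannelConfig) -> list[str]:
    """Corrupt a strand list: loss first, then per-base del/sub/ins edits."""
    rng = np.random.default_rng(config.rng_seed)
    out: list[str] = []
    for s in strands:
        if config.loss_rate and rng.random() < config.loss_rate:
            continue
        if not (config.sub_rate or config.ins_rate or config.del_rate):
            out.append(s)
            continue
        n = len(s)
        dels = rng.random(n) < config.del_rate
        subs = rng.random(n) < config.sub_rate
        inss = rng.random(n) < config.ins_rate
        parts: list[str] = []
        for i, b in enumerate(s):
            if not dels[i]:
                if subs[i]:
                    b = BASES[(BASES.index(b) + 1 + rng.integers(3)) % 4]
                parts.append(b)
            if inss[i]:
                parts.append(BASES[rng.integers(4)])
        out.append("".join(parts))
    return out


# ---------------------------------------------------------------------------
# soliton distributions


def ideal_soliton(k: int) -> np.ndarray:
    """rho(1) = 1/K, rho(d) = 1/(d(d-1)); index 0 unused, length K+1."""
    if k < 2:
        raise DomainError("K must be >= 2")
    rho = np.zeros(k + 1)
    rho[1] = 1.0 / k
    d = np.arange(2, k + 1)
    rho[2:] = 1.0 / (d * (d - 1.0))
    return rho


def robust_soliton(k: int, c: float = 0.1, delta: float = 0.5) -> np.ndarray:
    """Ideal soliton augmented with the tau spike near K/S, renormalised."""
    if k < 2:
        raise DomainError("K must be >= 2")
    if not (0.0 < delta < 1.0) or c <= 0.0:
        raise DomainError("need delta in (0,1) and c > 0")
    rho = ideal_soliton(k)
    s = c * np.log(k / delta) * np.sqrt(k)
    tau = np.zeros(k + 1)
    pivot = max(1, min(k, int(round(k / s))))
    d = np.arange(1, pivot)
    tau[1:pivot] = s / (k * d)
    tau[pivot] = s * np.log(s / delta) / k
    mu = rho + tau
    return mu / mu.sum()


# ---------------------------------------------------------------------------
# LT codec


@dataclass
class LTConfig:
    k: int
    epsilon: float = 0.25
    c: float = 0.1
    delta: float = 0.5

    def __post_init__(self):
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")

    @property
    def n_droplets(self) -> int:
        return int(np.ceil((1.0 + self.epsilon) * self.k))


@dataclass
class LTDroplet:
    neighbors: frozenset
    payload: np.ndarray


def lt_encode(chunks: np.ndarray, config: LTConfig, seed: int = 0) -> list[LTDroplet]:
    """Standard LT encoding: degree from the robust soliton, uniform chunks."""
    k = chunks.shape[0]
    if k != config.k:
        raise ConfigError("chunk count does not match LTConfig.k")
    rng = np.random.default_rng(seed)
    dist = robust_soliton(k, config.c, config.delta)
    degrees = rng.choice(k + 1, size=config.n_droplets, p=dist)
    droplets = []
    for d in degrees:
        idxs = rng.choice(k, size=int(d), replace=False)
        payload = np.bitwise_xor.reduce(chunks[idxs], axis=0)
        droplets.append(LTDroplet(neighbors=frozenset(int(i) for i in idxs),
                                  payload=payload.copy()))
    return droplets


def lt_decode(droplets: list[LTDroplet], k: int, chunk_bits: int):
    """Belief-propagation peeling; returns (chunks, recovered_mask)."""
    chunks = np.zeros((k, chunk_bits), dtype=np.uint8)
    recovered = np.zeros(k, dtype=bool)
    pending = [[set(d.neighbors), d.payload.copy()] for d in droplets]
    progress = True
    while progress:
        progress = False
        for item in pending:
            nbrs, payload = item
            resolved = [j for j in nbrs if recovered[j]]
            for j in resolved:
                payload ^= chunks[j]
                nbrs.discard(j)
            if len(nbrs) == 1:
                j = next(iter(nbrs))
                if not recovered[j]:
                    chunks[j] = payload
                    recovered[j] = True
                    progress = True
                nbrs.clear()
        pending = [it for it in pending if it[0]]
    return chunks, recovered


# ---------------------------------------------------------------------------
# recovery experiments


@dataclass
class RecoveryResult:
    codec: str
    error_kind: str
    level: float
    replicate: int
    chunk_recovery: float
    file_success: bool


def _rc_trial(encoded: EncodeResult, kind: str, level: float, seed: int) -> RecoveryResult:
    cfg = dict(rng_seed=seed)
    if kind == "loss":
        cfg["loss_rate"] = level
    elif kind == "deletion":
        cfg["del_rate"] = level
    elif kind == "insertion":
        cfg["ins_rate"] = level
    elif kind == "substitution":
        cfg["sub_rate"] = level
    else:
        raise ConfigError(f"unknown error kind {kind!r}")
    corrupted = apply_channel(encoded.strands, ChannelConfig(**cfg))
    data, report = decode(corrupted, k=encoded.k, m=encoded.m,
                          original_bit_length=encoded.chunkset.original_bit_length,
                          adapter_fwd=encoded.adapter_fwd,
                          adapter_rev=encoded.adapter_rev,
                          layout=encoded.layout,
                          row_capacity=encoded.row_capacity,
                          partial=True)
    return RecoveryResult("RC", kind, level, seed, report.chunk_recovery,
                          bool(report.file_ok))


def _lt_trial(chunks: np.ndarray, config: LTConfig, kind: str, level: float,
              seed: int) -> RecoveryResult:
    if kind != "loss":
        raise ConfigError("the LT baseline models strand loss only")
    droplets = lt_encode(chunks, config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    kept = [d for d in droplets if rng.random() >= level]
    _, recovered = lt_decode(kept, config.k, chunks.shape[1])
    frac = float(recovered.mean())
    return RecoveryResult("LT", kind, level, seed, frac, bool(recovered.all()))


def recovery_experiment(*, encoded: EncodeResult | None = None,
                        lt_chunks: np.ndarray | None = None,
                        lt_config: LTConfig | None = None,
                        error_kinds=("loss",),
                        levels=(0.0, 0.04, 0.08),
                        replicates: int = 20,
                        seed: int = 0) -> pd.DataFrame:
    """Sweep an error grid for RC (DNA-level) and/or LT (droplet-level).

    Every (kind, level, replicate) cell corrupts a fresh copy of the encoded
    strands with a derived seed and records the fraction of chunks recovered
    plus whole-file success.  Output is a tidy DataFrame ready for CSV.
    """
    rows: list[RecoveryResult] = []
    for kind in error_kinds:
        for level in levels:
            for rep in range(replicates):
                trial_seed = seed * 1_000_003 + hash((kind, float(level), rep)) % 997
                trial_seed = abs(trial_seed + rep)
                if encoded is not None:
                    rows.append(_rc_trial(encoded, kind, level, trial_seed))
                if lt_chunks is not None:
                    cfg = lt_config or LTConfig(k=lt_chunks.shape[0])
                    rows.append(_lt_trial(lt_chunks, cfg, kind, level, trial_seed))
    return pd.DataFrame(
        [dict(codec=r.codec, error_kind=r.error_kind, level=r.level,
              replicate=r.replicate, chunk_recovery=r.chunk_recovery,
              file_success=r.file_success) for r in rows])
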