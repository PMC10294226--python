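"""Sequence-constraint screening and the analytic run/degree models.

Detectors (GC content, homopolymer runs, micro-satellites) operate on ACGT
strings or on 2-bit index arrays; the array paths are the hot loop of the
encoder's equilibrium search.

The analytic side implements the Feller run-length approximation for the
probability that a random sequence stays below a homopolymer threshold, and
the normal approximation N(K/2, K/4) of the row-degree distribution of fair
random bit matrices.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

from ._seq import as_indices
from .errors import AlphabetError, ConfigError, DomainError


@dataclass
class ConstraintPolicy:
    """Thresholds used by screening and by the equilibrium search.

    Defaults encode run < 4 and GC in [45%, 55%], with micro-satellite
    screening of primitive tandem repeats (unit 2-6 nt, >= 3 copies spanning
    >= 9 nt).  GC bounds are inclusive and evaluated globally over the
    screened region.
    """

    max_homopolymer_run: int = 3
    gc_min: float = 0.45
    gc_max: float = 0.55
    microsat_unit_min: int = 2
    microsat_unit_max: int = 6
    microsat_min_copies: int = 3
    microsat_min_span: int = 9
    screen_microsatellites: bool = True
    screen_adapters: bool = True

    def __post_init__(self):
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ConfigError("need 0 <= gc_min <= gc_max <= 1")
        if self.max_homopolymer_run < 1:
            raise ConfigError("max_homopolymer_run must be >= 1")
        if self.microsat_unit_min < 2:
            raise ConfigError("microsat_unit_min must be >= 2 (unit 1 is a homopolymer)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConstraintPolicy":
        return cls(**d)


class MicrosatelliteHit(NamedTuple):
    start: int  # 0-based, half-open span [start, start + span)
    unit: str
    copies: int
    span: int


# ---------------------------------------------------------------------------
# detectors


def gc_content(seq) -> float:
    idx = as_indices(seq)
    if idx.size == 0:
        raise AlphabetError("empty sequence")
    return float((idx >= 2).sum()) / idx.size  # C=2, G=3


def max_homopolymer_run(seq) -> int:
    """Length of the longest run of one repeated base."""
    idx = as_indices(seq)
    if idx.size == 0:
        raise AlphabetError("empty sequence")
    if idx.size == 1:
        return 1
    # run boundaries where consecutive bases differ
    change = np.flatnonzero(idx[1:] != idx[:-1])
    edges = np.concatenate(([-1], change, [idx.size - 1]))
    return int(np.diff(edges).max())


def _primitive(unit: str) -> bool:
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[: p] * (n // p):
            return False
    return True


def find_microsatellites(seq, policy: ConstraintPolicy | None = None) -> list[MicrosatelliteHit]:
    """Maximal tandem repeats with a primitive unit of length 2..6.

    A hit at period ``u`` is a maximal stretch where seq[i] == seq[i+u],
    reported with its full span, the repeat unit, and the count of complete
    copies.  Non-primitive units (themselves repeats of a shorter unit,
    including single-base units) are dropped, so homopolymers never appear
    here and each repeat region is reported once per primitive period.
    """
    policy = policy or ConstraintPolicy()
    idx = as_indices(seq)
    if isinstance(seq, str):
        text = seq.upper()
    else:
        from ._seq import indices_to_seq

        text = indices_to_seq(idx)
    hits: list[MicrosatelliteHit] = []
    n = idx.size
    for u in range(policy.microsat_unit_min, policy.microsat_unit_max + 1):
        if n < 2 * u:
            continue
        eq = idx[u:] == idx[:-u]
        # maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            span = (e - s) + u
            copies = span // u
            if copies < policy.microsat_min_copies or span < policy.microsat_min_span:
                continue
            unit = text[s: s + u]
            if not _primitive(unit):
                continue
            hits.append(MicrosatelliteHit(start=int(s), unit=unit, copies=int(copies), span=int(span)))
    hits.sort(key=lambda h: (h.start, len(h.unit)))
    return hits


def passes_constraints(seq, policy: ConstraintPolicy | None = None) -> tuple[bool, list[str]]:
    """Screen one sequence; returns (ok, reasons for every failed check)."""
    policy = policy or ConstraintPolicy()
    idx = as_indices(seq)
    reasons: list[str] = []
    run = max_homopolymer_run(idx)
    if run > policy.max_homopolymer_run:
        reasons.append(f"homopolymer: run {run} > {policy.max_homopolymer_run}")
    gc = gc_content(idx)
    if not (policy.gc_min - 1e-12 <= gc <= policy.gc_max + 1e-12):
        reasons.append(f"gc: {gc:.4f} outside [{policy.gc_min}, {policy.gc_max}]")
    if policy.screen_microsatellites:
        ms = find_microsatellites(idx, policy)
        if ms:
            h = ms[0]
            reasons.append(f"microsatellite: {h.unit}x{h.copies} at {h.start}")
    return (not reasons, reasons)


def _fast_screen(idx: np.ndarray, policy: ConstraintPolicy,
                 gc_lo: float, gc_hi: float) -> bool:
    """Allocation-light screen for the equilibrium hot loop (no reasons)."""
    eq = idx[1:] == idx[:-1]
    r = policy.max_homopolymer_run
    if eq.size >= r:
        w = eq[: eq.size - r + 1]
        for j in range(1, r):
            w = w & eq[j: eq.size - r + 1 + j]
        if w.any():
            return False
    g = int((idx >= 2).sum())
    if not (gc_lo <= g <= gc_hi):
        return False
    if policy.screen_microsatellites and find_microsatellites(idx, policy):
        return False
    return True


# ---------------------------------------------------------------------------
# analytic models


def feller_x(p: float, m: int) -> float:
    """Feller root approximation x = 1 + q p^m + (m+1)(q p^m)^2."""
    if not (0.0 < p < 1.0):
        raise DomainError(f"p must be in (0, 1), got {p}")
    if m < 1:
        raise DomainError("m must be >= 1")
    q = 1.0 - p
    t = q * p ** m
    return 1.0 + t + (m + 1) * t * t


def feller_beta(p: float, m: int, x: float) -> float:
    """Feller prefactor beta = (1 - p x) / ((m + 1 - m x) q)."""
    if not (0.0 < p < 1.0):
        raise DomainError(f"p must be in (0, 1), got {p}")
    q = 1.0 - p
    den = (m + 1 - m * x) * q
    if den <= 0.0:
        raise DomainError("beta denominator non-positive; x too large for this m")
    return (1.0 - p * x) / den

def no_run_prob(p: float, m: int, l: int) -> float:
    """Approximate P(no success-run of length >= m in l Bernoulli(p) trials).

    Evaluates beta / x^(l+1) and clamps into [0, 1].
    """
    if l < 1:
        raise DomainError("l must be >= 1")
    x = feller_x(p, m)
    beta = feller_beta(p, m, x)
    return float(min(1.0, max(0.0, beta / x ** (l + 1))))


def homopolymer_Q(m: int, l: int) -> float:
    """Probability that a uniform random l-mer keeps every base's run < m+...

    Modelled as four independent per-base events, each a Bernoulli(0.25)
    no-run probability with run-length parameter ``m``:
    Q = no_run_prob(0.25, m, l) ** 4.  With m=4, l=700 this evaluates to
    about 2.5e-4 (0.025%), matching the strand-level compliance rate for a
    run-<4 policy.
    """
    if m < 1 or l < 1:
        raise DomainError("m and l must be >= 1")
    return no_run_prob(0.25, m, l) ** 4


def degree_pdf(x_val, k: int):
    """Density of the row-degree normal approximation N(K/2, K/4)."""
    if k < 1:
        raise DomainError("K must be >= 1")
    return norm.pdf(x_val, loc=k / 2.0, scale=np.sqrt(k / 4.0))
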