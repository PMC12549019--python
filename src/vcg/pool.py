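"""Oligomer pools: length-resolved concentration profiles.

A pool mixes short feedstock oligomers (monomers, dimers, ...) with long VCG
oligomers.  Both families follow exponential concentration profiles
``c(L) = c_hat * exp(-kappa * L)`` restricted to a length window; ``kappa = 0``
gives uniform profiles and a single-length window gives a delta profile.
Concentrations are stored in molar units throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "PoolSpec",
    "LengthDistribution",
    "build_distribution",
    "per_sequence_concentration",
    "amplitude_for_total",
]

_UNIT = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def parse_concentration(value) -> float:
    """Parse '0.1 mM' / '9.1uM' / plain numbers (molar) into molar units."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    for suffix, factor in sorted(_UNIT.items(), key=lambda kv: -len(kv[0])):
        if text.endswith(suffix):
            return float(text[: -len(suffix)]) * factor
    return float(text)


@dataclass(frozen=True)
class PoolSpec:
    """Exponential-window parameterization of feedstock and VCG profiles.

    ``chat_F``/``chat_V`` are concentration amplitudes (M), ``kappa_F``/
    ``kappa_V`` inverse decay lengths (1/nt), and the four ``L*`` bounds
    delimit the length windows (nt).
    """

    chat_F: float
    kappa_F: float
    LF_min: int
    LF_max: int
    chat_V: float
    kappa_V: float
    LV_min: int
    LV_max: int

    def __post_init__(self) -> None:
        if self.chat_F < 0 or self.chat_V < 0:
            raise ValueError("concentration amplitudes must be >= 0")
        if self.LF_min > self.LF_max or self.LV_min > self.LV_max:
            raise ValueError("length windows must be non-empty")
        if self.LF_max >= self.LV_min:
            raise ValueError(
                "feedstock window must lie strictly below the VCG window "
                f"(LF_max={self.LF_max} >= LV_min={self.LV_min})"
            )
        if self.LF_min < 1:
            raise ValueError("lengths must be >= 1")


@dataclass(frozen=True)
class LengthDistribution:
    """Total concentration (M) per oligomer length, split into feedstock and
    VCG windows."""

    c: dict
    feedstock_lengths: tuple
    vcg_lengths: tuple
    cF_tot: float = field(init=False)
    cV_tot: float = field(init=False)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.c.values()):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(
            self, "cF_tot", sum(self.c.get(L, 0.0) for L in self.feedstock_lengths)
        )
        object.__setattr__(
            self, "cV_tot", sum(self.c.get(L, 0.0) for L in self.vcg_lengths)
        )

    @property
    def lengths(self) -> tuple:
        return tuple(sorted(L for L, v in self.c.items() if v > 0))

    def __getitem__(self, L: int) -> float:
        return self.c.get(L, 0.0)

    @classmethod
    def from_concentrations(cls, c: dict, split_length: int) -> "LengthDistribution":
        """Build directly from a length->concentration map; lengths below
        ``split_length`` count as feedstock (the genome's L_U is the natural
        choice)."""
        feed = tuple(sorted(L for L in c if L < split_length))
        vcg = tuple(sorted(L for L in c if L >= split_length))
        return cls(c=dict(c), feedstock_lengths=feed, vcg_lengths=vcg)

    def scaled_vcg(self, cV_tot: float) -> "LengthDistribution":
        """Same pool with the VCG window rescaled to a new total (M)."""
        if self.cV_tot <= 0:
            raise ValueError("cannot rescale an empty VCG window")
        factor = cV_tot / self.cV_tot
        c = dict(self.c)
        for L in self.vcg_lengths:
            if L in c:
                c[L] *= factor
        return LengthDistribution(
            c=c,
            feedstock_lengths=self.feedstock_lengths,
            vcg_lengths=self.vcg_lengths,
        )


def build_distribution(spec: PoolSpec, genome_scales=None) -> LengthDistribution:
    """Evaluate the two exponential windows; zero elsewhere."""
    if genome_scales is not None and spec.LV_min < genome_scales.L_U:
        warnings.warn(
            f"VCG window starts below the genome's unique motif length "
            f"(LV_min={spec.LV_min} < L_U={genome_scales.L_U}); such oligomers "
            "carry no unique locus",
            stacklevel=2,
        )
    c: dict = {}
    for L in range(spec.LF_min, spec.LF_max + 1):
        c[L] = spec.chat_F * math.exp(-spec.kappa_F * L)
    for L in range(spec.LV_min, spec.LV_max + 1):
        c[L] = c.get(L, 0.0) + spec.chat_V * math.exp(-spec.kappa_V * L)
    return LengthDistribution(
        c=c,
        feedstock_lengths=tuple(range(spec.LF_min, spec.LF_max + 1)),
        vcg_lengths=tuple(range(spec.LV_min, spec.LV_max + 1)),
    )


def amplitude_for_total(total: float, kappa: float, L_min: int, L_max: int) -> float:
    """Amplitude ``c_hat`` such that the window sums to ``total`` molar."""
    weight = sum(math.exp(-kappa * L) for L in range(L_min, L_max + 1))
    return total / weight


def per_sequence_concentration(dist: LengthDistribution, L: int, genome_scales) -> float:
    """Concentration of one specific sequence of length ``L``:
    ``c_s(L) = c(L) / C(L)`` with the combinatorial multiplicity ``C``."""
    c = dist[L]
    if c == 0.0:
        return 0.0
    return c / genome_scales.multiplicity(L)
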