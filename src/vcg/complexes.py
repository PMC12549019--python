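"""Coarse-grained complexes of up to four RNA strands.

Strand arrangements are tracked by lengths and alignment indices only; the
sequence content enters through combinatorial multiplicities.  Five classes of
complexes are distinguished:

* ``duplex``      -- one Crick (bottom) + one Watson (top) strand;
* ``ternary``     -- one Crick template hosting two Watson strands;
* ``quat31``      -- one Crick template hosting three Watson strands;
* ``quat22l``     -- two Crick + two Watson strands, the right Watson strand
                     bridging both Crick strands (left-tilted);
* ``quat22r``     -- two Crick + two Watson strands, the left Watson strand
                     bridging both Crick strands (right-tilted).

Energies follow a simplified nearest-neighbor model: each full block of two
Watson-Crick pairs contributes ``gamma`` (< 0), each dangling-end block
``gamma/2``; a nick (two strands abutting on a template) closes a full block.
Dissociation constants follow ``K_d = c_std**(n-1) * exp(E)`` with ``E`` in
units of kT, and the effective association constant ``Ka_eff = C / K_d``
absorbs the combinatorial multiplicity ``C`` of the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

__all__ = [
    "EnergyModel",
    "ComplexConfig",
    "Geometry",
    "Nick",
    "geometry",
    "hybridization_energy",
    "multiplicity",
    "dissociation_constant",
    "effective_association",
    "rotate22",
    "enumerate_configs",
    "configs_dataframe",
]

KINDS = ("duplex", "ternary", "quat31", "quat22l", "quat22r")


@dataclass(frozen=True)
class EnergyModel:
    """Energy and rate parameters of the hybridization/ligation model.

    ``gamma`` is the energy (kT) of one matching nearest-neighbor block and
    ``gamma_mm`` the penalty per block containing a mismatch (used only by the
    stochastic simulator's 'penalized' policy).  ``t0`` is the encounter
    timescale, the elementary time unit; ``k_lig`` the templated-ligation rate
    constant.  ``k_lig_mono``/``k_lig_oligo`` split the ligation rate between
    monomer-incorporating and oligomer-only ligations (kinetic suppression);
    they default to ``k_lig``.
    """

    gamma: float = -2.5
    gamma_mm: float = 25.0
    c_std: float = 1.0
    t0: float = 1.0
    k_lig: float = 1e-12
    k_lig_mono: float | None = None
    k_lig_oligo: float | None = None

    def __post_init__(self) -> None:
        if self.gamma >= 0:
            raise ValueError("gamma must be < 0 (stabilizing)")
        if self.gamma_mm <= 0:
            raise ValueError("gamma_mm must be > 0 (destabilizing)")
        if min(self.k_lig, self.lig_rate_mono, self.lig_rate_oligo) < 0:
            raise ValueError("ligation rates must be >= 0")

    @property
    def lig_rate_mono(self) -> float:
        return self.k_lig if self.k_lig_mono is None else self.k_lig_mono

    @property
    def lig_rate_oligo(self) -> float:
        return self.k_lig if self.k_lig_oligo is None else self.k_lig_oligo

    @property
    def k_enc(self) -> float:
        """Encounter rate constant 1/(c_std * t0)."""
        return 1.0 / (self.c_std * self.t0)


class ComplexConfig(NamedTuple):
    """A coarse-grained strand arrangement.

    ``lengths`` orders the strands as (L_C, L_W) for duplexes,
    (L_C, L_W1, L_W2[, L_W3]) for ternary/3-1 complexes, and
    (L_C1, L_C2, L_W1, L_W2) for 2-2 complexes; ``aligns`` holds the
    alignment indices (i[, j[, k]]) measured from the left end of the (first)
    Crick strand.
    """

    kind: str
    lengths: tuple
    aligns: tuple

    @property
    def n_strands(self) -> int:
        return len(self.lengths)


class Nick(NamedTuple):
    """A ligation-competent junction: educt lengths, their overlaps with the
    template spanning the nick, and the template length."""

    le1: int
    le2: int
    lo1: int
    lo2: int
    template: int


class Geometry(NamedTuple):
    overlaps: tuple
    dangles: tuple  # (d_l, d_m..., d_r) as 0/1 flags
    chain: tuple  # ((partner_length, overlap_with_chain), ...) for multiplicity
    nicks: tuple  # ligation-competent junctions


def geometry(cfg: ComplexConfig) -> Geometry:
    """Overlaps, dangling-end flags, multiplicity chain, and nicks of ``cfg``.

    A dangling-end flag is 0 when the respective junction is flush (no
    overhanging base), 1 otherwise; a middle flag ``d_m = 0`` marks a nick.
    """
    kind = cfg.kind
    if kind == "duplex":
        (Lc, Lw), (i,) = cfg.lengths, cfg.aligns
        lo = min(Lc, i + Lw) - max(i, 0)
        dl = 0 if i == 0 else 1
        dr = 0 if i + Lw == Lc else 1
        return Geometry((lo,), (dl, dr), ((Lw, lo),), ())
    if kind == "ternary":
        (Lc, Lw1, Lw2), (i, j) = cfg.lengths, cfg.aligns
        lo1 = i + Lw1 - max(i, 0)
        lo2 = min(j + Lw2, Lc) - j
        dl = 0 if i == 0 else 1
        dm = 0 if i + Lw1 == j else 1
        dr = 0 if j + Lw2 == Lc else 1
        nicks = (Nick(Lw1, Lw2, lo1, lo2, Lc),) if dm == 0 else ()
        return Geometry((lo1, lo2), (dl, dm, dr), ((Lw1, lo1), (Lw2, lo2)), nicks)
    if kind == "quat31":
        (Lc, Lw1, Lw2, Lw3), (i, j, k) = cfg.lengths, cfg.aligns
        lo1 = i + Lw1 - max(i, 0)
        lo2 = Lw2
        lo3 = min(Lc, k + Lw3) - k
        dl = 0 if i == 0 else 1
        dm1 = 0 if i + Lw1 == j else 1
        dm2 = 0 if j + Lw2 == k else 1
        dr = 0 if k + Lw3 == Lc else 1
        nicks = []
        if dm1 == 0:
            nicks.append(Nick(Lw1, Lw2, lo1, lo2, Lc))
        if dm2 == 0:
            nicks.append(Nick(Lw2, Lw3, lo2, lo3, Lc))
        return Geometry(
            (lo1, lo2, lo3),
            (dl, dm1, dm2, dr),
            ((Lw1, lo1), (Lw2, lo2), (Lw3, lo3)),
            tuple(nicks),
        )
    if kind == "quat22l":
        (Lc1, Lc2, Lw1, Lw2), (i, j, k) = cfg.lengths, cfg.aligns
        lo1 = i + Lw1 - max(i, 0)
        lo2 = Lc1 - j
        lo3 = min(j + Lw2, k + Lc2) - k
        dl = 0 if i == 0 else 1
        dm1 = 0 if i + Lw1 == j else 1
        dm2 = 0 if k == Lc1 else 1
        dr = 0 if j + Lw2 == k + Lc2 else 1
        nicks = []
        if dm1 == 0:  # Watson-side nick, templated by C1
            nicks.append(Nick(Lw1, Lw2, lo1, lo2, Lc1))
        if dm2 == 0:  # Crick-side nick, templated by the bridging W2
            nicks.append(Nick(Lc1, Lc2, lo2, lo3, Lw2))
        return Geometry(
            (lo1, lo2, lo3),
            (dl, dm1, dm2, dr),
            ((Lw1, lo1), (Lw2, lo2), (Lc2, lo3)),
            tuple(nicks),
        )
    if kind == "quat22r":
        (Lc1, Lc2, Lw1, Lw2), (i, j, k) = cfg.lengths, cfg.aligns
        lo1 = Lc1 - max(i, 0)
        lo2 = i + Lw1 - k
        lo3 = min(k + Lc2, j + Lw2) - j
        dl = 0 if i == 0 else 1
        dm1 = 0 if i + Lw1 == j else 1
        dm2 = 0 if k == Lc1 else 1
        dr = 0 if j + Lw2 == k + Lc2 else 1
        nicks = []
        if dm1 == 0:  # Watson-side nick, templated by the bridging... C2 spans it
            nicks.append(Nick(Lw1, Lw2, lo2, lo3, Lc2))
        if dm2 == 0:  # Crick-side nick, templated by the bridging W1
            nicks.append(Nick(Lc1, Lc2, lo1, lo2, Lw1))
        return Geometry(
            (lo1, lo2, lo3),
            (dl, dm1, dm2, dr),
            ((Lw1, lo1), (Lc2, lo2), (Lw2, lo3)),
            tuple(nicks),
        )
    raise ValueError(f"unknown complex kind {kind!r}")


def hybridization_energy(
    cfg: ComplexConfig, model: EnergyModel, geo: Geometry | None = None
) -> float:
    """Total hybridization energy in kT (negative = stable).

    Depends only on overlap lengths and dangling flags, never on absolute
    strand lengths: each overlap of length Lo contributes Lo-1 full blocks,
    each dangling end gamma/2, each gap two dangling ends, and each closed
    junction (nick) one extra full block.
    """
    g = model.gamma
    if geo is None:
        geo = geometry(cfg)
    n_over = len(geo.overlaps)
    E = g * (sum(geo.overlaps) - n_over)
    dl, *dms, dr = geo.dangles
    E += 0.5 * g * (dl + dr + 2 * sum(dms))
    E += g * sum(1 - dm for dm in dms)
    return E


def rotate22(cfg: ComplexConfig) -> ComplexConfig:
    """The 180-degree-rotated representation of a 2-2 complex (an involution;
    the tilt class is preserved and strand roles swap C1<->W2, C2<->W1)."""
    if cfg.kind not in ("quat22l", "quat22r"):
        raise ValueError("rotation is defined for 2-2 complexes only")
    (Lc1, Lc2, Lw1, Lw2), (i, j, k) = cfg.lengths, cfg.aligns
    return ComplexConfig(
        kind=cfg.kind,
        lengths=(Lw2, Lw1, Lc2, Lc1),
        aligns=(j - k + Lw2 - Lc2, j + Lw2 - Lc1, j + Lw2 - i - Lw1),
    )


def _is_rotation_symmetric(cfg: ComplexConfig) -> bool:
    return cfg.kind in ("quat22l", "quat22r") and rotate22(cfg) == cfg


def multiplicity(cfg: ComplexConfig, scales, geo: Geometry | None = None) -> float:
    """Combinatorial multiplicity of the configuration.

    The template's multiplicity is multiplied, for every partner strand added
    along the hybridization chain, by the number of admissible (mismatch-free)
    partner sequences: C(L)/4**Lo while the overlap is below the minimal
    unique length, and exactly one partner once the overlap pins a unique
    locus.  Symmetry corrections: x1/2 for equal-length duplexes and for
    rotation-symmetric 2-2 complexes.
    """
    if geo is None:
        geo = geometry(cfg)
    m = float(scales.multiplicity(cfg.lengths[0]))
    for partner_len, lo in geo.chain:
        if lo < scales.L_U_min:
            m *= scales.multiplicity(partner_len) / 4**lo
    if cfg.kind == "duplex" and cfg.lengths[0] == cfg.lengths[1]:
        m *= 0.5
    elif _is_rotation_symmetric(cfg):
        m *= 0.5
    return m


def dissociation_constant(cfg: ComplexConfig, model: EnergyModel) -> float:
    """K_d = c_std**(n-1) * exp(E/kT), in M**(n-1)."""
    n = cfg.n_strands
    return model.c_std ** (n - 1) * math.exp(hybridization_energy(cfg, model))


def effective_association(cfg: ComplexConfig, scales, model: EnergyModel) -> float:
    """Effective association constant Ka_eff = C / K_d (per-sequence mass
    action times the number of sequence realizations)."""
    return multiplicity(cfg, scales) / dissociation_constant(cfg, model)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def _iter_duplexes(lengths) -> Iterator[ComplexConfig]:
    for Lc in lengths:
        for Lw in lengths:
            if Lw > Lc:
                continue
            for i in range(-(Lw - 1), Lc):
                yield ComplexConfig("duplex", (Lc, Lw), (i,))


def _iter_ternaries(lengths) -> Iterator[ComplexConfig]:
    for Lc in lengths:
        for Lw1 in lengths:
            for i in range(-(Lw1 - 1), Lc - Lw1):
                for Lw2 in lengths:
                    for j in range(i + Lw1, Lc):
                        yield ComplexConfig("ternary", (Lc, Lw1, Lw2), (i, j))


def _iter_quat31(lengths) -> Iterator[ComplexConfig]:
    for Lc in lengths:
        for Lw1 in lengths:
            for Lw2 in lengths:
                for i in range(-(Lw1 - 1), Lc - Lw1 - Lw2):
                    for j in range(i + Lw1, Lc - Lw2):
                        for Lw3 in lengths:
                            for k in range(j + Lw2, Lc):
                                yield ComplexConfig(
                                    "quat31", (Lc, Lw1, Lw2, Lw3), (i, j, k)
                                )


def _iter_quat22(lengths) -> Iterator[ComplexConfig]:
    # left-tilted: W2 bridges C1 and C2
    for Lc1 in lengths:
        for Lw1 in lengths:
            for i in range(-(Lw1 - 1), Lc1 - Lw1):
                for Lw2 in lengths:
                    for j in range(i + Lw1, Lc1):
                        for Lc2 in lengths:
                            for k in range(Lc1, j + Lw2):
                                cfg = ComplexConfig(
                                    "quat22l", (Lc1, Lc2, Lw1, Lw2), (i, j, k)
                                )
                                if cfg <= rotate22(cfg):
                                    yield cfg
    # right-tilted: W1 bridges C1 and C2
    for Lc1 in lengths:
        for Lw1 in lengths:
            for i in range(max(Lc1 - Lw1 + 1, -(Lw1 - 1)), Lc1):
                for Lc2 in lengths:
                    for k in range(Lc1, i + Lw1):
                        for Lw2 in lengths:
                            for j in range(i + Lw1, k + Lc2):
                                cfg = ComplexConfig(
                                    "quat22r", (Lc1, Lc2, Lw1, Lw2), (i, j, k)
                                )
                                if cfg <= rotate22(cfg):
                                    yield cfg


def enumerate_configs(
    lengths_present: Iterable[int], max_order: int = 4
) -> Iterator[ComplexConfig]:
    """Yield every geometrically valid complex configuration over the given
    strand lengths exactly once (2-2 complexes deduplicated to the
    lexicographically smaller of the two rotated representations)."""
    lengths = sorted(set(int(L) for L in lengths_present))
    if not lengths:
        raise ValueError("need at least one strand length")
    if min(lengths) < 1:
        raise ValueError("strand lengths must be >= 1")
    if max_order < 2:
        return
    yield from _iter_duplexes(lengths)
    if max_order >= 3:
        yield from _iter_ternaries(lengths)
    if max_order >= 4:
        yield from _iter_quat31(lengths)
        yield from _iter_quat22(lengths)


def configs_dataframe(lengths_present, scales, model: EnergyModel, max_order: int = 4):
    """Audit table of enumerated configs (kind, lengths, aligns, overlaps,
    energy, multiplicity, K_d).  Intended for small length sets."""
    import pandas as pd

    rows = []
    for cfg in enumerate_configs(lengths_present, max_order):
        geo = geometry(cfg)
        rows.append(
            {
                "kind": cfg.kind,
                "lengths": "|".join(map(str, cfg.lengths)),
                "aligns": "|".join(map(str, cfg.aligns)),
                "overlaps": "|".join(map(str, geo.overlaps)),
                "energy_kT": hybridization_energy(cfg, model),
                "multiplicity": multiplicity(cfg, scales),
                "Kd": dissociation_constant(cfg, model),
            }
        )
    return pd.DataFrame(rows)
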