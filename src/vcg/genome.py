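"""Circular genomes, motif statistics, and Metropolis-Hastings sequence design.

A virtual circular genome (VCG) stores a circular sequence together with its
reverse complement.  Two length scales characterize how motifs are distributed
along it:

* the unique motif length ``L_U`` -- the smallest ``L`` such that every motif
  of length ``L`` occurs at most once across the genome and its complement,
  so any such motif addresses a unique genomic locus;
* the exhaustive coverage length ``L_E`` -- the largest ``L`` for which all
  ``4**L`` possible motifs occur.

Genomes with prescribed ``(L_E, L_U)`` are generated by Metropolis-Hastings
sampling with the motif entropy acting as an effective Hamiltonian.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

ALPHABET = "ACGU"
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

__all__ = [
    "CircularGenome",
    "GenomeLengthScales",
    "MotifSpectrum",
    "MHConfig",
    "SampleResult",
    "enumerate_motifs",
    "motif_entropy",
    "length_scales",
    "lu_min",
    "le_max",
    "sample_genome",
    "read_fasta",
    "write_fasta",
]


@dataclass(frozen=True)
class CircularGenome:
    """A circular RNA sequence; the complement strand is always implied."""

    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if not seq:
            raise ValueError("genome sequence must be non-empty")
        if set(seq) - set(ALPHABET):
            raise ValueError(f"genome alphabet must be {{A,C,G,U}}, got {self.sequence!r}")
        object.__setattr__(self, "sequence", seq)

    @property
    def L_G(self) -> int:
        return len(self.sequence)

    @property
    def complement(self) -> str:
        """Reverse complement (base-wise complement, then reversed), circular."""
        return self.sequence.translate(_COMPLEMENT)[::-1]

    def motif_counts(self, L: int) -> Counter:
        """Occurrence counts of length-``L`` motifs over all ``2*L_G`` circular
        start positions (``L_G`` per strand).  Palindromic coincidences count
        once per strand."""
        if not 1 <= L <= self.L_G:
            raise ValueError(f"motif length must satisfy 1 <= L <= L_G, got {L}")
        counts: Counter = Counter()
        for strand in (self.sequence, self.complement):
            doubled = strand + strand
            for start in range(self.L_G):
                counts[doubled[start : start + L]] += 1
        return counts

    def contains_motif(self, motif: str) -> bool:
        """Whether ``motif`` occurs on the circular genome or its complement."""
        if len(motif) > self.L_G:
            return False
        for strand in (self.sequence, self.complement):
            if motif in strand + strand[: len(motif) - 1]:
                return True
        return False


@dataclass(frozen=True)
class GenomeLengthScales:
    """Characteristic motif length scales of a circular genome (all in nt)."""

    L_G: int
    L_U: int
    L_E: int
    L_U_min: int
    L_E_max: int

    def multiplicity(self, L: int) -> int:
        """Combinatorial multiplicity C(L): number of distinct sequences a
        coarse-grained oligomer of length ``L`` stands for (``4**L`` below
        the minimal unique length, ``2*L_G`` at or above it)."""
        if L < 1:
            raise ValueError("oligomer length must be >= 1")
        return 4**L if L < self.L_U_min else 2 * self.L_G


@dataclass(frozen=True)
class MotifSpectrum:
    """Relative motif frequencies at one motif length, with their entropy."""

    L: int
    counts: dict
    frequencies: dict = field(init=False)
    S: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        freqs = {m: n / total for m, n in self.counts.items()}
        entropy = -sum(f * math.log(f, 4) for f in freqs.values())
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "S", entropy)

    @property
    def n_distinct(self) -> int:
        return len(self.counts)


def enumerate_motifs(genome: CircularGenome, L: int) -> MotifSpectrum:
    """Count length-``L`` motifs across both strands and normalize."""
    return MotifSpectrum(L=L, counts=dict(genome.motif_counts(L)))


def motif_entropy(genome: CircularGenome, L: int) -> float:
    """Motif entropy S(L) = -sum_i f_i log4 f_i.

    Base-4 logs make the exhaustive-regime bound ``S_max(L) = L`` exact: a
    genome containing all ``4**L`` motifs at equal frequency has ``S(L) = L``.
    """
    return enumerate_motifs(genome, L).S


def s_max(L: int, L_G: int) -> float:
    """Upper bound on the motif entropy at motif length ``L``."""
    return min(L, math.log(2 * L_G, 4))


def lu_min(L_G: int) -> int:
    """Smallest length at which a motif can be uniquely addressable: only
    ``2*L_G`` distinct motifs fit on genome plus complement, so ``4**L`` must
    reach ``2*L_G``."""
    if L_G < 1:
        raise ValueError("L_G must be >= 1")
    return math.ceil(round(math.log(2 * L_G, 4), 12))


def le_max(L_G: int) -> int:
    """Largest length at which all ``4**L`` motifs can possibly be present."""
    if L_G < 1:
        raise ValueError("L_G must be >= 1")
    return math.floor(round(math.log(2 * L_G, 4), 12))


def length_scales(genome: CircularGenome) -> GenomeLengthScales:
    """Measure ``L_U`` and ``L_E`` by exhaustive circular motif scans.

    ``L_U`` is the smallest L with all motif counts <= 1 (a repeat at L+1
    implies a repeat at L, so the first such L is valid for all longer
    motifs).  ``L_E`` is the largest L with all ``4**L`` motifs present.
    """
    L_G = genome.L_G
    L_U = None
    for L in range(1, L_G + 1):
        if max(genome.motif_counts(L).values()) <= 1:
            L_U = L
            break
    if L_U is None:
        raise ValueError("no unique motif length exists (repeats persist up to L_G)")
    L_E = 0
    for L in range(1, L_G + 1):
        if len(genome.motif_counts(L)) == 4**L:
            L_E = L
        else:
            break
    return GenomeLengthScales(
        L_G=L_G, L_U=L_U, L_E=L_E, L_U_min=lu_min(L_G), L_E_max=le_max(L_G)
    )


# ---------------------------------------------------------------------------
# Metropolis-Hastings genome design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MHConfig:
    """Settings for the Metropolis-Hastings genome sampler.

    ``beta`` is the inverse effective temperature of the Metropolis rule
    (moves that lower the Hamiltonian are always accepted, uphill moves with
    probability ``exp(-beta * dH)``).  The cut-and-paste move, which relocates
    a circular segment, is 10x more likely than a point mutation.
    """

    beta: float = 1e-5
    n_steps: int = 10_000
    p_cutpaste: float = 10 / 11
    seed: int = 0
    hamiltonian: str = "max-diversity"  # or "entropy-reduction"
    stop_rule: str = "target-scales-reached"  # or "plateau"

    def __post_init__(self) -> None:
        if not 0 < self.p_cutpaste < 1:
            raise ValueError("p_cutpaste must lie in (0, 1)")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.hamiltonian not in ("max-diversity", "entropy-reduction"):
            raise ValueError(f"unknown hamiltonian {self.hamiltonian!r}")
        if self.stop_rule not in ("target-scales-reached", "plateau"):
            raise ValueError(f"unknown stop_rule {self.stop_rule!r}")


@dataclass(frozen=True)
class SampleResult:
    genome: CircularGenome
    converged: bool
    n_steps: int
    hamiltonian: float


def _hamiltonian(seq: str, cfg: MHConfig, target_le: int, target_lu: int) -> float:
    g = CircularGenome(seq)
    if cfg.hamiltonian == "max-diversity":
        # minimize H = -S(L_E^target) - S(L_U^target): drives both scales to
        # their maximally diverse values
        return -motif_entropy(g, target_le) - motif_entropy(g, target_lu)
    # entropy reduction across the intermediate range L_E..L_U
    return sum(motif_entropy(g, L) for L in range(target_le, target_lu + 1))


def _targets_reached(seq: str, target_le: int, target_lu: int) -> bool:
    g = CircularGenome(seq)
    try:
        scales = length_scales(g)
    except ValueError:
        return False
    return scales.L_E == target_le and scales.L_U == target_lu


def sample_genome(
    L_G: int,
    target_lu: int | None = None,
    target_le: int | None = None,
    cfg: MHConfig = MHConfig(),
    initial: CircularGenome | None = None,
) -> SampleResult:
    """Sample a circular genome of length ``L_G`` with target length scales.

    Defaults target the maximally diverse genome (``L_E = L_E_max``,
    ``L_U = L_U_min``).  Deterministic under a fixed ``cfg.seed``.  If the
    stop rule is not met within ``cfg.n_steps``, the best-so-far genome is
    returned with ``converged=False``.
    """
    if target_lu is None:
        target_lu = lu_min(L_G)
    if target_le is None:
        target_le = le_max(L_G)
    if not 1 <= target_le < target_lu <= L_G:
        raise ValueError("targets must satisfy 1 <= L_E < L_U <= L_G")
    rng = np.random.default_rng(cfg.seed)
    if initial is not None:
        seq = initial.sequence
        if len(seq) != L_G:
            raise ValueError("initial genome length does not match L_G")
    else:
        seq = "".join(rng.choice(list(ALPHABET), size=L_G))
    H = _hamiltonian(seq, cfg, target_le, target_lu)
    best_seq, best_H = seq, H
    plateau = 0
    converged = _targets_reached(seq, target_le, target_lu)
    steps_used = 0
    for step in range(1, cfg.n_steps + 1):
        steps_used = step
        if rng.random() < cfg.p_cutpaste and L_G >= 3:
            # cut a segment of uniform length from a uniform circular start
            # and reinsert it at a uniform position of the remainder
            seg_len = int(rng.integers(1, L_G))
            start = int(rng.integers(0, L_G))
            doubled = seq + seq
            segment = doubled[start : start + seg_len]
            rest = doubled[start + seg_len : start + L_G]
            pos = int(rng.integers(0, len(rest) + 1))
            new_seq = rest[:pos] + segment + rest[pos:]
        else:
            pos = int(rng.integers(0, L_G))
            base = ALPHABET[int(rng.integers(0, 4))]
            while base == seq[pos]:
                base = ALPHABET[int(rng.integers(0, 4))]
            new_seq = seq[:pos] + base + seq[pos + 1 :]
        new_H = _hamiltonian(new_seq, cfg, target_le, target_lu)
        dH = new_H - H
        if dH <= 0 or rng.random() < math.exp(-cfg.beta * dH):
            seq, H = new_seq, new_H
            plateau = 0
        else:
            plateau += 1
        if H < best_H:
            best_seq, best_H = seq, H
        if cfg.stop_rule == "target-scales-reached":
            if _targets_reached(seq, target_le, target_lu):
                converged = True
                break
        elif plateau >= 500:
            converged = True
            break
    if cfg.stop_rule == "target-scales-reached" and converged:
        final, final_H = seq, H
    else:
        final, final_H = best_seq, best_H
    return SampleResult(
        genome=CircularGenome(final),
        converged=converged,
        n_steps=steps_used,
        hamiltonian=final_H,
    )


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def write_fasta(genome: CircularGenome, path) -> None:
    """Write the genome as a single FASTA record; the description carries the
    measured length scales."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    scales = length_scales(genome)
    rec = SeqRecord(
        Seq(genome.sequence),
        id=f"circular_genome_L{genome.L_G}",
        description=f"circular L_G={scales.L_G} L_U={scales.L_U} L_E={scales.L_E}",
    )
    seqio_write([rec], str(path), "fasta")


def read_fasta(path) -> CircularGenome:
    from Bio.SeqIO import read as seqio_read

    rec = seqio_read(str(path), "fasta")
    return CircularGenome(str(rec.seq))


#: The 16-nt example genome used throughout: contains every monomer and dimer
#: at equal frequency (L_E = 2) and addresses every locus with trimers
#: (L_U = 3).
EXAMPLE_GENOME = CircularGenome("AAAGAGGACACGGCAU")
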