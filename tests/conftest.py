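"""Shared fixtures and brute-force oracles.

The oracles here deliberately re-derive quantities from first principles
(explicit strand placements, explicit sequence matching) so that the
package's coarse-grained bookkeeping can be checked against an independent
path.
"""

from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, database=None
)
settings.load_profile("deterministic")

from vcg.complexes import EnergyModel
from vcg.genome import EXAMPLE_GENOME, CircularGenome, length_scales


@pytest.fixture(scope="session")
def genome16() -> CircularGenome:
    return EXAMPLE_GENOME


@pytest.fixture(scope="session")
def scales16(genome16):
    return length_scales(genome16)


@pytest.fixture(scope="session")
def model() -> EnergyModel:
    return EnergyModel()


# ---------------------------------------------------------------------------
# Brute-force shape enumeration: place strands of given lengths on two rows
# at arbitrary offsets, keep connected mismatch-free-geometry arrangements,
# canonicalize under translation and 180-degree rotation.
# ---------------------------------------------------------------------------


def _normalize(shape):
    lo = min(s for _, s, _ in shape)
    return tuple(sorted((r, s - lo, L) for r, s, L in shape))


def _flip(shape):
    hi = max(s + L for _, s, L in shape)
    return tuple(sorted((1 - r, hi - (s + L), L) for r, s, L in shape))


def canonical_shape(shape):
    """Canonical form of a set of (row, start, length) strand intervals."""
    a = _normalize(shape)
    b = _normalize(_flip(shape))
    return min(a, b)


def _valid_shape(strands):
    """Same-row strands must not overlap; every strand needs >=1 paired
    column; the pairing graph must be connected."""
    for r in (0, 1):
        spans = sorted((s, s + L) for rr, s, L in strands if rr == r)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                return False
    n = len(strands)
    paired = [[False] * n for _ in range(1)]
    adj = [set() for _ in range(n)]
    for i, (ri, si, Li) in enumerate(strands):
        for j, (rj, sj, Lj) in enumerate(strands):
            if j <= i or ri == rj:
                continue
            if min(si + Li, sj + Lj) - max(si, sj) >= 1:
                adj[i].add(j)
                adj[j].add(i)
    if any(not a for a in adj):
        return False
    seen = {0}
    stack = [0]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == n


def brute_force_shapes(lengths, n_strands):
    """All distinct connected two-row arrangements of ``n_strands`` strands
    with lengths from ``lengths``, one representative per rotation orbit."""
    lengths = sorted(set(lengths))
    Lmax = max(lengths)
    window = range(-3 * Lmax, 3 * Lmax + 1)  # first strand pinned at 0
    shapes = set()
    splits = {2: [(1, 1)], 3: [(1, 2), (2, 1)], 4: [(1, 3), (2, 2), (3, 1)]}
    for n_bot, n_top in splits[n_strands]:
        for bot_lens in itertools.product(lengths, repeat=n_bot):
            for top_lens in itertools.product(lengths, repeat=n_top):
                free = n_bot + n_top - 1
                for starts in itertools.product(window, repeat=free):
                    starts = (0,) + starts
                    bot = starts[:n_bot]
                    top = starts[n_bot:]
                    strands = tuple(
                        [(0, s, L) for s, L in zip(bot, bot_lens)]
                        + [(1, s, L) for s, L in zip(top, top_lens)]
                    )
                    if _valid_shape(strands):
                        shapes.add(canonical_shape(strands))
    return shapes


def config_shape(cfg):
    """Map a ComplexConfig to its canonical (row, start, length) shape."""
    if cfg.kind == "duplex":
        (Lc, Lw), (i,) = cfg.lengths, cfg.aligns
        strands = ((0, 0, Lc), (1, i, Lw))
    elif cfg.kind == "ternary":
        (Lc, Lw1, Lw2), (i, j) = cfg.lengths, cfg.aligns
        strands = ((0, 0, Lc), (1, i, Lw1), (1, j, Lw2))
    elif cfg.kind == "quat31":
        (Lc, Lw1, Lw2, Lw3), (i, j, k) = cfg.lengths, cfg.aligns
        strands = ((0, 0, Lc), (1, i, Lw1), (1, j, Lw2), (1, k, Lw3))
    elif cfg.kind in ("quat22l", "quat22r"):
        (Lc1, Lc2, Lw1, Lw2), (i, j, k) = cfg.lengths, cfg.aligns
        strands = ((0, 0, Lc1), (0, k, Lc2), (1, i, Lw1), (1, j, Lw2))
    else:  # pragma: no cover
        raise ValueError(cfg.kind)
    return canonical_shape(strands)


# ---------------------------------------------------------------------------
# Sequence-level motif helpers for the example genome
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGU", "UGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@pytest.fixture(scope="session")
def partner_counts(genome16):
    """For each Watson length: (window start, window content) -> number of
    genome-compatible Watson strands carrying that content there."""
    counts = {}
    for L in range(1, 9):
        d = {}
        for w in motif_list(genome16, L):
            for a in range(L):
                for b in range(a + 1, L + 1):
                    key = (a, w[a:b])
                    d[key] = d.get(key, 0) + 1
        counts[L] = d
    return counts


def motif_list(genome: CircularGenome, L: int):
    """Distinct length-L motifs across genome and complement (circular)."""
    out = set()
    for strand in (genome.sequence, genome.complement):
        doubled = strand + strand
        for s in range(genome.L_G):
            out.add(doubled[s : s + L])
    return sorted(out)
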