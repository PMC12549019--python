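"""Canonical study conditions as ready-to-run configurations.

Writes the 16-nt example genome and YAML run configurations for the standard
pool scenarios: single-length pools (monomers + one VCG length), the
two-length (tetramer/octamer) pool, dimer-containing feedstock, and the
kinetically suppressed multi-length pool.
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml

from .genome import EXAMPLE_GENOME, write_fasta

__all__ = ["make_fixtures"]


def _single_length_config(L_V: int, ratio: float) -> dict:
    return {
        "genome": {"fasta": "genome16.fa"},
        "model": {"gamma": -2.5, "gamma_mm": 25.0, "k_lig": 1e-12},
        "pool": {
            "concentrations": {"1": "0.1 mM", str(L_V): f"{1e-4 * ratio} M"},
        },
        "mode": "adiabatic",
        "sweep": {
            "axis": "cV_tot",
            "start": 1e-8,
            "stop": 1e-5,
            "points_per_decade": 8,
        },
    }


def make_fixtures(outdir) -> list:
    """Write genome FASTA + configuration files; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fasta = outdir / "genome16.fa"
    write_fasta(EXAMPLE_GENOME, fasta)
    written.append(fasta)

    # single-length pools: monomer feedstock plus one VCG length
    for L_V in (6, 7, 8):
        cfg = _single_length_config(L_V, 1e-3)
        path = outdir / f"single_length_L{L_V}.yaml"
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
        written.append(path)

    # two-length tetramer/octamer pool
    two_len = {
        "genome": {"fasta": "genome16.fa"},
        "model": {"gamma": -2.5},
        "pool": {"concentrations": {"1": "0.1 mM", "4": "7.4 pM", "8": "0.1 uM"}},
        "mode": "adiabatic",
    }
    (outdir / "two_length_pool.yaml").write_text(yaml.safe_dump(two_len, sort_keys=False))
    written.append(outdir / "two_length_pool.yaml")

    # monomer + dimer feedstock, single-length VCG; dimers at 10% of
    # monomers corresponds to kappa_F = ln 10
    dimer_feed = {
        "genome": {"fasta": "genome16.fa"},
        "model": {"gamma": -2.5},
        "pool": {
            "chat_F": 0.091e-3 * math.e ** math.log(10),
            "kappa_F": math.log(10),
            "LF_min": 1,
            "LF_max": 2,
            "chat_V": 1e-7,
            "kappa_V": 0.0,
            "LV_min": 7,
            "LV_max": 7,
        },
        "mode": "adiabatic",
        "sweep": {"axis": "cV_tot", "start": 1e-9, "stop": 1e-5, "points_per_decade": 8},
    }
    (outdir / "dimer_feedstock.yaml").write_text(yaml.safe_dump(dimer_feed, sort_keys=False))
    written.append(outdir / "dimer_feedstock.yaml")

    # kinetic suppression, single length: reactive monomers 0.091 mM,
    # non-reactive dimers 9.1 uM
    supp_single = {
        "genome": {"fasta": "genome16.fa"},
        "model": {"gamma": -2.5, "k_lig_mono": 1e-12, "k_lig_oligo": 0.0},
        "pool": {"concentrations": {"1": "0.091 mM", "2": "9.1 uM", "8": "1 uM"}},
        "mode": "adiabatic",
        "kinetic_suppression": True,
        "sweep": {"axis": "cV_tot", "start": 1e-9, "stop": 1e-4, "points_per_decade": 8},
    }
    (outdir / "suppression_single_length.yaml").write_text(yaml.safe_dump(supp_single, sort_keys=False))
    written.append(outdir / "suppression_single_length.yaml")

    # kinetic suppression, uniform multi-length pool 3..9
    conc = {"1": "0.091 mM", "2": "9.1 uM"}
    for L in range(3, 10):
        conc[str(L)] = f"{1e-7 / 7} M"
    supp_multi = {
        "genome": {"fasta": "genome16.fa"},
        "model": {"gamma": -2.5, "k_lig_mono": 1e-12, "k_lig_oligo": 0.0},
        "pool": {"concentrations": conc},
        "mode": "adiabatic",
        "kinetic_suppression": True,
        "sweep": {"axis": "cV_tot", "start": 1e-8, "stop": 1e-5, "points_per_decade": 8},
    }
    (outdir / "suppression_multilength.yaml").write_text(yaml.safe_dump(supp_multi, sort_keys=False))
    written.append(outdir / "suppression_multilength.yaml")
    return written
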