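"""Disruptive-guanine classification and SNP-load comparison.

Within a four-run motif, a guanine is *disruptive* when a substitution
there is predicted to abolish quadruplex formation: every G of a 3-nt
run, the second and third G of a 4-nt run, and the middle G of a 5-nt
run; G's in runs of six or more are non-disruptive (longer runs retain
enough guanines to rebuild a tetrad).  The classification is only
defined for motifs with exactly four G-runs — a fifth run is a "spare
tire" that can substitute for a broken one, so such motifs are rejected.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .g4_scanner import G4Motif
from .interval_stats import snps_by_chrom

log = logging.getLogger(__name__)

#: disruptive positions within a run (0-based, motif-strand orientation)
_DISRUPTIVE_OFFSETS = {3: (0, 1, 2), 4: (1, 2), 5: (2,)}

REQUIRED_RUNS = 4

RATIO_COLUMNS = [
    "chrom",
    "n_motifs_4run",
    "n_disruptive_pos",
    "n_nondisruptive_pos",
    "snps_disruptive",
    "snps_nondisruptive",
    "ratio",
]


class SpareTireError(ValueError):
    """Raised for motifs with a run count other than four."""


@dataclass(frozen=True)
class DisruptiveAnnotation:
    motif: G4Motif
    disruptive_positions: frozenset[int]
    non_disruptive_positions: frozenset[int]


def disruptive_offsets(run_length: int) -> tuple[int, ...]:
    return _DISRUPTIVE_OFFSETS.get(run_length, ())


def classify_motif_positions(motif: G4Motif) -> DisruptiveAnnotation:
    """Split the G positions of a four-run motif into disruptive and not.

    Positions are genome (+ strand) coordinates; run-internal offsets are
    mirrored for - strand motifs so the rule applies in the structural,
    motif-strand orientation.  Loop positions belong to neither class.
    """
    if motif.n_runs != REQUIRED_RUNS:
        raise SpareTireError(
            f"spare-tire rule: classification undefined for {motif.n_runs}-run motif"
        )
    disruptive: set[int] = set()
    non_disruptive: set[int] = set()
    for s, e in motif.g_runs:
        length = e - s
        offs = set(disruptive_offsets(length))
        if motif.strand == "-":
            offs = {length - 1 - o for o in offs}
        for k in range(length):
            (disruptive if k in offs else non_disruptive).add(s + k)
    return DisruptiveAnnotation(motif, frozenset(disruptive), frozenset(non_disruptive))


def disruptive_snp_ratio(
    motifs: Sequence[G4Motif], snps: Iterable, by_chrom: bool = True
) -> pd.DataFrame:
    """Ratio of disruptive to non-disruptive SNP density, per chromosome.

    Density = SNPs on positions of a class / number of positions of the
    class (per bp).  Motifs with a run count other than four are ignored;
    an input with none at all is an error.  Scopes with zero
    non-disruptive SNP density get ratio NaN and are logged as undefined.
    With ``by_chrom=False`` a single row (chrom='all') pools everything.
    """
    four_run = [m for m in motifs if m.n_runs == REQUIRED_RUNS]
    if not four_run:
        raise ValueError("disruptive_snp_ratio: no motifs with exactly four G-runs")
    pos = snps if isinstance(snps, dict) else snps_by_chrom(snps)

    acc: dict[str, dict] = {}
    for m in four_run:
        ann = classify_motif_positions(m)
        d = acc.setdefault(m.chrom or ".", {"n": 0, "disr": set(), "nond": set()})
        d["n"] += 1
        d["disr"] |= ann.disruptive_positions
        d["nond"] |= ann.non_disruptive_positions

    rows = []
    for chrom in sorted(acc):
        d = acc[chrom]
        snp_set = {int(p) for p in pos.get(chrom, ())}
        rows.append(
            {
                "chrom": chrom,
                "n_motifs_4run": d["n"],
                "n_disruptive_pos": len(d["disr"]),
                "n_nondisruptive_pos": len(d["nond"]),
                "snps_disruptive": len(d["disr"] & snp_set),
                "snps_nondisruptive": len(d["nond"] & snp_set),
            }
        )
    if not by_chrom:
        pooled = {
            "chrom": "all",
            **{
                k: sum(r[k] for r in rows)
                for k in RATIO_COLUMNS[1:-1]
            },
        }
        rows = [pooled]
    for r in rows:
        dens_d = r["snps_disruptive"] / r["n_disruptive_pos"] if r["n_disruptive_pos"] else np.nan
        dens_n = (
            r["snps_nondisruptive"] / r["n_nondisruptive_pos"]
            if r["n_nondisruptive_pos"]
            else np.nan
        )
        r["ratio"] = dens_d / dens_n if np.isfinite(dens_n) and dens_n > 0 else np.nan
        if not np.isfinite(r["ratio"]):
            log.info("disruptive_snp_ratio: ratio undefined on %s", r["chrom"])
    return pd.DataFrame(rows, columns=RATIO_COLUMNS)
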