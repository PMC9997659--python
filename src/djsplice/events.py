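"""Cassette-exon events and percent-spliced-in (PSI) quantification.

A cassette event is a junction trio: two inclusion junctions flanking
the cassette exon plus one skipping junction whose intron spans exactly
the union of the two inclusion introns and the cassette. Per sample,

    psi_hat = mean(c_inc1, c_inc2) / (mean(c_inc1, c_inc2) + c_skip)

The MEAN of the two inclusion junctions (not their sum) keeps the
estimator unbiased for the true inclusion fraction when both flanks have
equal expected depth. psi_hat is set to missing when the denominator
falls below ``min_cov`` reads (default 10, mirroring the junction
filter).
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dje import bh_fdr
from .junctions import Junction, JunctionTable

__all__ = [
    "CassetteEvent",
    "detect_cassette_events",
    "compute_psi",
    "psi_matrix",
    "correlate_events",
    "write_events_bed",
]


@dataclass(frozen=True)
class CassetteEvent:
    """Inclusion/exclusion junction trio defining one cassette exon."""

    gene_id: str
    inc1: Junction
    inc2: Junction
    skip: Junction
    cassette: tuple[str, int, int, str]  # chrom, start, end (1-based incl.), strand

    def __post_init__(self) -> None:
        if not (self.skip.intron_start == self.inc1.intron_start
                and self.skip.intron_end == self.inc2.intron_end
                and self.inc1.intron_end + 1 <= self.inc2.intron_start - 1):
            raise ValueError("junction trio does not satisfy cassette geometry")

    @property
    def event_id(self) -> str:
        c, s, e, st = self.cassette
        return f"{self.gene_id}:{c}:{s}-{e}:{st}"


def detect_cassette_events(table: JunctionTable,
                           statuses: pd.DataFrame) -> list[CassetteEvent]:
    """Enumerate junction trios satisfying the cassette geometry per gene.

    The inclusion flanks may be non-annotated while the skipping
    junction is annotated — the signature of an unannotated cassette
    exon.
    """
    by_gene: dict[str, list[Junction]] = {}
    for j in table.junctions:
        gid = statuses.at[j.key, "gene_id"] if j.key in statuses.index else None
        if gid is not None and not (isinstance(gid, float) and np.isnan(gid)):
            by_gene.setdefault(gid, []).append(j)
    events = []
    for gid, juncs in by_gene.items():
        juncs = sorted(juncs, key=lambda j: (j.intron_start, j.intron_end))
        skips = {(j.intron_start, j.intron_end): j for j in juncs}
        for j1, j2 in itertools.combinations(juncs, 2):
            if j1.intron_end + 1 > j2.intron_start - 1:
                continue
            skip = skips.get((j1.intron_start, j2.intron_end))
            if skip is None or skip is j1 or skip is j2:
                continue
            cassette = (j1.chrom, j1.intron_end + 1, j2.intron_start - 1,
                        skip.strand)
            events.append(CassetteEvent(gid, j1, j2, skip, cassette))
    events.sort(key=lambda e: e.event_id)
    return events


def compute_psi(event: CassetteEvent, table: JunctionTable,
                min_cov: float = 10.0) -> pd.Series:
    """Per-sample psi_hat for one event (NaN below ``min_cov`` coverage)."""
    for j in (event.inc1, event.inc2, event.skip):
        if j.key not in table.counts.index:
            raise KeyError(f"junction {j.key} absent from table")
    c1 = table.counts.loc[event.inc1.key].astype(float)
    c2 = table.counts.loc[event.inc2.key].astype(float)
    cs = table.counts.loc[event.skip.key].astype(float)
    inc = (c1 + c2) / 2.0
    denom = inc + cs
    psi = inc / denom.where(denom > 0)
    psi[denom < min_cov] = np.nan
    return psi.rename(event.event_id)


def psi_matrix(events: list[CassetteEvent], table: JunctionTable,
               min_cov: float = 10.0) -> pd.DataFrame:
    """Events x samples PSI matrix (values in [0,1] or missing)."""
    if not events:
        return pd.DataFrame(columns=table.samples)
    return pd.DataFrame([compute_psi(e, table, min_cov) for e in events])


def correlate_events(psi: pd.DataFrame, event_a: str | None = None,
                     event_b: str | None = None,
                     min_samples: int = 3) -> pd.DataFrame:
    """Pearson correlation between event PSI profiles, BH across pairs.

    Pairwise-complete samples are used; pairs with a constant PSI vector
    get ``r = NaN`` and are flagged ``degenerate``. When ``event_a`` and
    ``event_b`` are given only that pair's record is returned (its FDR
    still adjusted across all testable pairs in ``psi``).
    """
    rows = []
    for a, b in itertools.combinations(psi.index, 2):
        xa, xb = psi.loc[a], psi.loc[b]
        ok = xa.notna() & xb.notna()
        n = int(ok.sum())
        if n < min_samples:
            continue
        x, y = xa[ok].to_numpy(), xb[ok].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"event_a": a, "event_b": b, "r": np.nan,
                         "p": np.nan, "n_used": n, "degenerate": True})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"event_a": a, "event_b": b, "r": float(r),
                     "p": float(p), "n_used": n, "degenerate": False})
    out = pd.DataFrame(rows, columns=["event_a", "event_b", "r", "p",
                                      "n_used", "degenerate"])
    out["FDR"] = np.nan
    ok = ~out["degenerate"] if len(out) else out["degenerate"]
    if len(out) and ok.any():
        out.loc[ok, "FDR"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    if event_a is not None and event_b is not None:
        pair = out[((out.event_a == event_a) & (out.event_b == event_b)) |
                   ((out.event_a == event_b) & (out.event_b == event_a))]
        if pair.empty:
            raise KeyError(f"pair ({event_a}, {event_b}) not testable")
        return pair.reset_index(drop=True)
    return out


def write_events_bed(events: list[CassetteEvent],
                     path: str | os.PathLike) -> None:
    """BED-like TSV of cassette intervals (1-based inclusive) + junction keys."""
    rows = [{
        "chrom": e.cassette[0], "start": e.cassette[1], "end": e.cassette[2],
        "event_id": e.event_id, "strand": e.cassette[3], "gene_id": e.gene_id,
        "inc1": e.inc1.key, "inc2": e.inc2.key, "skip": e.skip.key,
    } for e in events]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
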