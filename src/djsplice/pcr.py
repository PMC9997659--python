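"""In-silico RT-PCR: primer search, amplicon sizing, insert translation.

Primers are matched exactly (no mismatch model — the 18-23-mer primers
used for cassette-exon genotyping at stringent annealing justify this;
documented limitation). A product is formed wherever the forward primer
matches the sense strand upstream of a reverse-complement match of the
reverse primer, up to a length cap; multiple binding sites yield all
pairwise products, mirroring multi-band gels.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "PrimerPair",
    "Amplicon",
    "FrameshiftError",
    "find_amplicons",
    "translate_insert",
    "interval_length",
    "amplicon_report",
]

_DNA = set("ACGT")


class FrameshiftError(ValueError):
    """Insert length not divisible by 3: translation frame is broken."""


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if len(p) < 10:
                raise ValueError("primers must be >= 10 nt")
            if not set(p) <= _DNA:
                raise ValueError(f"primer {p!r} not over alphabet ACGT")


@dataclass(frozen=True)
class Amplicon:
    """A PCR product located on the template (1-based inclusive)."""

    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _find_all(template: str, query: str) -> list[int]:
    hits, i = [], template.find(query)
    while i != -1:
        hits.append(i)
        i = template.find(query, i + 1)
    return hits


def find_amplicons(template: str, primers: PrimerPair,
                   max_length: int = 5000) -> list[Amplicon]:
    """All exact-match PCR products on ``template``, sorted by length.

    The forward primer must match the sense strand; the reverse primer
    binds the antisense strand, i.e. its reverse complement must appear
    on the sense strand downstream of the forward match. Products longer
    than ``max_length`` are dropped. Zero products is a valid outcome.
    """
    template = template.upper()
    fwd = primers.forward.upper()
    rev_rc = str(Seq(primers.reverse.upper()).reverse_complement())
    products = []
    for i in _find_all(template, fwd):
        for j in _find_all(template, rev_rc):
            end = j + len(rev_rc)  # exclusive
            if i <= j and end - i >= max(len(fwd), len(rev_rc)):
                if end - i <= max_length:
                    products.append(Amplicon(i + 1, end, template[i:end]))
    products.sort(key=lambda a: (a.length, a.start))
    return products


def translate_insert(cds_without: str, cds_with: str) -> str:
    """Peptide inserted by a contiguous in-frame insertion.

    Both sequences must share reading frame from their first base and
    differ by a single contiguous insert whose length is divisible by 3
    (otherwise :class:`FrameshiftError`). The inserted residues are
    located by protein-level prefix/suffix comparison, so inserts need
    not start exactly on a codon boundary as long as the flanking
    residues are preserved. An in-frame stop in the insert is flagged
    with a warning ('*' retained in the returned peptide).
    """
    a, b = cds_without.upper(), cds_with.upper()
    ins_len = len(b) - len(a)
    if ins_len < 0:
        raise ValueError("cds_with must be at least as long as cds_without")
    if ins_len % 3 != 0:
        raise FrameshiftError(
            f"insert length {ins_len} nt is not divisible by 3")
    if ins_len == 0:
        if a != b:
            raise ValueError("equal-length sequences differ: not an insertion")
        return ""
    pa = str(Seq(a[: len(a) - len(a) % 3]).translate())
    pb = str(Seq(b[: len(b) - len(b) % 3]).translate())
    d = len(pb) - len(pa)
    if d != ins_len // 3:
        raise ValueError("sequences do not differ by a clean in-frame insert")
    p = 0
    while p < len(pa) and pa[p] == pb[p]:
        p += 1
    # leftmost placement: insert = pb[p:p+d]; remainder must match
    if pb[p + d:] != pa[p:]:
        raise ValueError("sequences do not differ by a single contiguous insert")
    peptide = pb[p:p + d]
    if "*" in peptide:
        warnings.warn("insert contains an in-frame stop codon",
                      RuntimeWarning, stacklevel=2)
    return peptide


def interval_length(chrom: str, start: int, end: int,
                    convention: str = "one_based_inclusive") -> int:
    """Length in nt of a genomic interval under the stated convention."""
    if convention == "one_based_inclusive":
        if end < start:
            raise ValueError("end must be >= start (inclusive convention)")
        return end - start + 1
    if convention == "half_open":
        if end <= start:
            raise ValueError("end must be > start (half-open convention)")
        return end - start
    raise ValueError(f"unknown convention {convention!r}")


def amplicon_report(templates: dict[str, str], primers: PrimerPair,
                    path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Amplicon table (template, start, end, length) across templates."""
    rows = []
    for name, tpl in templates.items():
        for amp in find_amplicons(tpl, primers):
            rows.append({"template": name, "start": amp.start,
                         "end": amp.end, "length_bp": amp.length})
        if not find_amplicons(tpl, primers):
            rows.append({"template": name, "start": None, "end": None,
                         "length_bp": 0})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
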