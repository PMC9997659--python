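"""Synthetic study-condition generators.

Three seeded generators produce every input the pipeline consumes:

* :func:`simulate_cohort` — a two-group junction-count cohort over an
  annotated multi-gene model in which selected genes carry a hidden
  (non-annotated) cassette exon with group-dependent inclusion fraction
  psi. Counts are negative-binomial around library-size-scaled expected
  junction coverage; the cassette's two inclusion junctions are absent
  from the emitted annotation while its skipping junction is annotated.

* :func:`simulate_trace` — magnetic-tweezers force-ramp bead-height
  traces. Force rises linearly, F(t) = f_start + r*t; each protein
  domain unfolds once at a stochastic force drawn from Bell-Evans
  kinetics (rate k(F) = k0*exp(F*dx/kBT)) under the ramp, adding a
  step of ``step_size`` nm to bead height; Gaussian sampling noise is
  added per point.

* :func:`make_pcr_fixture` — inclusion/skipping template pairs plus a
  flanking primer pair for in-silico RT-PCR, sized so the skipping
  amplicon is 183 bp with a 51-nt cassette (talin-1 exon-17b-like) or
  the inclusion amplicon is 278 bp with a 57-nt cassette
  (calsyntenin-1 exon-11-like).

All three are deterministic given their spec (including seed).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .junctions import GeneAnnotation, GeneModel, Junction, JunctionTable

__all__ = [
    "CohortSpec",
    "TraceSpec",
    "DomainSpec",
    "PcrFixture",
    "ForceRampTrace",
    "simulate_cohort",
    "simulate_trace",
    "make_pcr_fixture",
    "write_cohort",
    "write_trace",
    "write_pcr_fixture",
    "KBT_ROOM",
]

#: Thermal energy at room temperature, pN*nm.
KBT_ROOM = 4.114

_EXON_LEN = 100
_INTRON_LEN = 200
_GENE_SPACING = 10_000
_TLN1_CASSETTE_LEN = 51
_CLSTN1_CASSETTE_LEN = 57

# Printed RT-PCR primer pairs flanking the cassette exons.
TLN1_PRIMERS = ("CAAGCAGCTGGGAACGTG", "CTGAAGTCCCGAGTCCTCTG")
CLSTN1_PRIMERS = ("GACTCTCTATGTGGATGGCACG", "CCTTGCAGGTATACAGACAGTCG")

_STOPS = {"TAA", "TAG", "TGA"}


class InvalidSpecError(ValueError):
    """Raised for generator specs violating their invariants."""


# ---------------------------------------------------------------------------
# Junction-count cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of a two-group synthetic junction-count cohort.

    ``cassette_genes`` lists ``(gene_id, psi_A, psi_B)`` triples: true
    inclusion fractions of the hidden cassette exon per group.
    ``psi_profiles`` optionally overrides group-level psi with a
    per-sample inclusion fraction array (length = total samples), e.g.
    to program anti-coupled events or trait-linked inclusion.
    """

    n_genes: int = 10
    n_samples_per_group: tuple[int, int] = (60, 60)
    junctions_per_gene: int = 6
    cassette_genes: Sequence[tuple[str, float, float]] = (("gene_1", 0.7, 0.05),)
    gene_abundance: float = 100.0
    nb_dispersion: float = 0.05
    libsize_range: tuple[float, float] = (8e5, 1.2e6)
    seed: int = 0
    psi_profiles: Mapping[str, Sequence[float]] | None = None

    def validate(self) -> None:
        if self.n_genes <= 0 or self.junctions_per_gene < 2:
            raise InvalidSpecError("need n_genes >= 1 and >= 2 junctions/gene")
        if min(self.n_samples_per_group) <= 0:
            raise InvalidSpecError("sample counts must be strictly positive")
        if self.gene_abundance <= 0:
            raise InvalidSpecError("gene_abundance must be > 0")
        if self.nb_dispersion < 0:
            raise InvalidSpecError("nb_dispersion must be >= 0")
        if not (0 < self.libsize_range[0] <= self.libsize_range[1]):
            raise InvalidSpecError("invalid libsize_range")
        gene_ids = {f"gene_{i + 1}" for i in range(self.n_genes)}
        n_total = sum(self.n_samples_per_group)
        for gid, pa, pb in self.cassette_genes:
            if gid not in gene_ids:
                raise InvalidSpecError(f"unknown cassette gene {gid!r}")
            if not (0 <= pa <= 1 and 0 <= pb <= 1):
                raise InvalidSpecError("psi must lie in [0, 1]")
        for gid, prof in (self.psi_profiles or {}).items():
            arr = np.asarray(prof, dtype=float)
            if arr.shape != (n_total,):
                raise InvalidSpecError(
                    f"psi profile for {gid!r} must have length {n_total}")
            if ((arr < 0) | (arr > 1)).any():
                raise InvalidSpecError("psi profile values must lie in [0, 1]")


def _gene_structure(gene_index: int, n_junctions: int, cassette: bool,
                    strand: str) -> GeneModel:
    """Linear chain of n_junctions+1 exons of 100 nt separated by 200-nt introns."""
    off = gene_index * _GENE_SPACING + 1
    exons = []
    for i in range(n_junctions + 1):
        s = off + i * (_EXON_LEN + _INTRON_LEN)
        exons.append((s, s + _EXON_LEN - 1))
    gid = f"gene_{gene_index + 1}"
    return GeneModel(gid, "chrS", strand, {f"{gid}.t1": tuple(exons)})


def _cassette_geometry(gene: GeneModel, cassette_len: int = _TLN1_CASSETTE_LEN
                       ) -> dict:
    """Place the hidden cassette exon centred in the middle intron."""
    exons = gene.transcripts[f"{gene.gene_id}.t1"]
    c = len(exons) // 2 - 1  # 0-based index of the skipped intron
    up_end = exons[c][1]
    down_start = exons[c + 1][0]
    intron_start, intron_end = up_end + 1, down_start - 1
    mid = (intron_start + intron_end) // 2
    cass_start = mid - cassette_len // 2
    cass_end = cass_start + cassette_len - 1
    strand = gene.strand
    return {
        "skip": Junction(gene.chrom, strand, intron_start, intron_end),
        "inc1": Junction(gene.chrom, strand, intron_start, cass_start - 1),
        "inc2": Junction(gene.chrom, strand, cass_end + 1, intron_end),
        "cassette": (gene.chrom, cass_start, cass_end, strand),
        "intron_index": c,
    }


def simulate_cohort(spec: CohortSpec) -> tuple[JunctionTable, GeneAnnotation, dict]:
    """Simulate a two-group junction-count cohort with hidden cassette exons.

    Returns ``(table, annotation, truth)``. The annotation contains every
    constitutive junction (including each cassette gene's skipping
    junction) but never the cassette exon itself; the table additionally
    carries the two non-annotated inclusion junctions per cassette gene.
    ``truth`` records programmed psi per sample, junction keys, group
    labels and differential status.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_a, n_b = spec.n_samples_per_group
    n_total = n_a + n_b
    samples = [f"A{i + 1}" for i in range(n_a)] + [f"B{i + 1}" for i in range(n_b)]
    groups = ["A"] * n_a + ["B"] * n_b

    cassette_ids = {gid for gid, _, _ in spec.cassette_genes}
    genes = []
    for gi in range(spec.n_genes):
        gid = f"gene_{gi + 1}"
        # cassette genes sit on the reverse strand (talin-1-like); the rest
        # alternate so both orientations are exercised
        strand = "-" if gid in cassette_ids else ("+" if gi % 2 == 0 else "-")
        genes.append(_gene_structure(gi, spec.junctions_per_gene, gid in
                                     cassette_ids, strand))
    annotation = GeneAnnotation(genes)

    libsizes = rng.uniform(*spec.libsize_range, size=n_total)
    scale = libsizes / np.mean(spec.libsize_range)

    psi_by_gene: dict[str, np.ndarray] = {}
    for gid, pa, pb in spec.cassette_genes:
        if spec.psi_profiles and gid in spec.psi_profiles:
            psi_by_gene[gid] = np.asarray(spec.psi_profiles[gid], dtype=float)
        else:
            psi_by_gene[gid] = np.array([pa] * n_a + [pb] * n_b, dtype=float)

    juncs: list[Junction] = []
    mu_rows: list[np.ndarray] = []
    truth_genes: dict[str, dict] = {}
    for g in genes:
        gid = g.gene_id
        exons = g.transcripts[f"{gid}.t1"]
        geom = _cassette_geometry(g) if gid in psi_by_gene else None
        for i in range(len(exons) - 1):
            j = Junction(g.chrom, g.strand, exons[i][1] + 1, exons[i + 1][0] - 1)
            usage = np.ones(n_total)
            if geom is not None and i == geom["intron_index"]:
                usage = 1.0 - psi_by_gene[gid]  # skipping junction
            juncs.append(j)
            mu_rows.append(spec.gene_abundance * usage * scale)
        if geom is not None:
            psi = psi_by_gene[gid]
            for key in ("inc1", "inc2"):
                juncs.append(geom[key])
                mu_rows.append(spec.gene_abundance * psi * scale)
            truth_genes[gid] = {
                "psi_per_sample": psi.tolist(),
                "psi_A": float(np.mean(psi[:n_a])),
                "psi_B": float(np.mean(psi[n_a:])),
                "differential": bool(abs(np.mean(psi[:n_a]) -
                                         np.mean(psi[n_a:])) > 1e-12),
                "inclusion_junctions": [geom["inc1"].key, geom["inc2"].key],
                "skipping_junction": geom["skip"].key,
                "cassette_interval": list(geom["cassette"]),
            }

    mu = np.vstack(mu_rows)
    counts = _nb_draw(rng, mu, spec.nb_dispersion)
    df = pd.DataFrame(counts, index=[j.key for j in juncs], columns=samples)
    table = JunctionTable(juncs, df, pd.Series(libsizes, index=samples))
    truth = {
        "samples": samples,
        "groups": groups,
        "genes": truth_genes,
        "spec": {k: v for k, v in asdict(spec).items() if k != "psi_profiles"},
    }
    return table, annotation, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mu, var = mu + phi*mu^2); Poisson when phi == 0."""
    if dispersion == 0:
        return rng.poisson(mu)
    size_param = 1.0 / dispersion
    out = np.zeros_like(mu, dtype=int)
    pos = mu > 0
    p = size_param / (size_param + mu[pos])
    out[pos] = rng.negative_binomial(size_param, p)
    return out


# ---------------------------------------------------------------------------
# Force-ramp traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainSpec:
    """Bell-Evans parameters of one unfolding domain.

    k0: zero-force unfolding rate (1/s); dx: distance to the transition
    state (nm); step_size: bead-height increase on unfolding (nm).
    """

    k0: float
    dx: float
    step_size: float

    def modal_force(self, loading_rate: float, kbt: float = KBT_ROOM) -> float:
        """Closed-form modal ramp-unfolding force (prefactor corrections
        neglected): F* = (kBT/dx) * ln(r*dx / (k0*kBT))."""
        return (kbt / self.dx) * math.log(
            loading_rate * self.dx / (self.k0 * kbt))


@dataclass
class TraceSpec:
    """Design of one force-ramp scan.

    Defaults mirror the instrument regime the detector targets:
    1 pN/s loading rate, 200 Hz sampling, ~1 nm height noise, forces
    capped at 100 pN.
    """

    loading_rate: float = 1.0  # pN/s
    f_start: float = 1.0  # pN
    f_max: float = 40.0  # pN
    sample_rate: float = 200.0  # Hz
    noise_sd: float = 1.0  # nm
    domains: Sequence[DomainSpec] = (
        DomainSpec(k0=2.8e-3, dx=5.0, step_size=22.0),   # R3-like, F* ~ 5 pN
        DomainSpec(k0=1.28e-5, dx=3.0, step_size=25.0),  # R2-like, F* ~ 15 pN
        DomainSpec(k0=2.5e-6, dx=2.0, step_size=28.0),   # R1-like, F* ~ 25 pN
    )
    kbt: float = KBT_ROOM  # pN*nm
    seed: int = 0

    def validate(self) -> None:
        if not (self.f_start < self.f_max <= 100.0):
            raise InvalidSpecError("need f_start < f_max <= 100 pN")
        if self.sample_rate <= 0 or self.loading_rate < 0:
            raise InvalidSpecError("rates must be positive")
        if self.noise_sd < 0 or self.kbt <= 0:
            raise InvalidSpecError("noise_sd >= 0 and kbt > 0 required")
        for d in self.domains:
            if d.k0 <= 0 or d.dx <= 0 or d.step_size <= 0:
                raise InvalidSpecError("domain k0, dx, step_size must be > 0")


@dataclass
class ForceRampTrace:
    """Uniformly sampled bead-height series under a linear force ramp."""

    time: np.ndarray  # s
    height: np.ndarray  # nm
    f_start: float  # pN
    loading_rate: float  # pN/s

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


def _sample_unfolding_force(rng: np.random.Generator, d: DomainSpec,
                            r: float, f_start: float, kbt: float) -> float:
    """Invert the Bell-Evans ramp survival function at a uniform deviate."""
    u = rng.uniform()
    a = d.dx / kbt
    # S(F) = exp(-(k0/(r*a)) * (exp(a F) - exp(a f_start)))
    val = math.exp(a * f_start) + (r * a / d.k0) * (-math.log(u))
    return math.log(val) / a


def simulate_trace(spec: TraceSpec) -> tuple[ForceRampTrace, dict]:
    """Simulate one force-increase scan; returns (trace, truth).

    Each domain unfolds at most once; domains whose sampled unfolding
    force exceeds ``f_max`` stay folded and are marked unresolved in the
    truth record.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    duration = ((spec.f_max - spec.f_start) / spec.loading_rate
                if spec.loading_rate > 0 else 10.0)
    n = int(math.floor(duration * spec.sample_rate)) + 1
    t = np.arange(n) / spec.sample_rate
    height = np.zeros(n)
    events = []
    for i, d in enumerate(spec.domains):
        if spec.loading_rate == 0:
            f_unf = math.inf  # constant-force scans never resolve here
        else:
            f_unf = _sample_unfolding_force(rng, d, spec.loading_rate,
                                            spec.f_start, spec.kbt)
        t_unf = (f_unf - spec.f_start) / spec.loading_rate \
            if spec.loading_rate > 0 else math.inf
        resolved = f_unf <= spec.f_max and t_unf <= t[-1]
        if resolved:
            height[t >= t_unf] += d.step_size
        events.append({
            "domain": i,
            "force_pN": float(f_unf) if math.isfinite(f_unf) else None,
            "time_s": float(t_unf) if math.isfinite(t_unf) else None,
            "step_size_nm": d.step_size,
            "resolved": bool(resolved),
        })
    if spec.noise_sd > 0:
        height = height + rng.normal(0.0, spec.noise_sd, size=n)
    trace = ForceRampTrace(t, height, spec.f_start, spec.loading_rate)
    truth = {
        "n_resolved": sum(e["resolved"] for e in events),
        "events": events,
        "spec": {
            "loading_rate": spec.loading_rate, "f_start": spec.f_start,
            "f_max": spec.f_max, "sample_rate": spec.sample_rate,
            "noise_sd": spec.noise_sd, "kbt": spec.kbt, "seed": spec.seed,
            "domains": [asdict(d) for d in spec.domains],
        },
    }
    return trace, truth


# ---------------------------------------------------------------------------
# RT-PCR fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcrFixture:
    """Inclusion/skipping template pair with a flanking primer pair.

    ``template_inclusion`` equals ``template_skipping`` with ``cassette``
    inserted at ``insert_pos`` (0-based offset into the skipping
    template); both primers bind exactly once per template.
    """

    template_inclusion: str
    template_skipping: str
    primer_fwd: str
    primer_rev: str
    cassette: str
    insert_pos: int


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    out = []
    while len(out) < n_codons:
        codon = _random_seq(rng, 3)
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _occurs_once(template: str, primer: str) -> bool:
    return template.count(primer) == 1 and template.count(_revcomp(primer)) == 0


def make_pcr_fixture(mode: str = "TLN1", seed: int = 0,
                     flank: int = 60) -> PcrFixture:
    """Build an in-silico RT-PCR fixture.

    ``mode='TLN1'``: talin-1 exon-17b-like — the printed TLN1 primer pair
    delimits a 183 bp product on the skipping template; the cassette is
    51 nt (stop-free in frame 0), so inclusion yields 234 bp.
    ``mode='CLSTN1'``: calsyntenin-1 exon-11-like — 278 bp on the
    inclusion template with a 57-nt cassette (221 bp on skipping).

    Flanking sequence is random but seeded, regenerated until each
    primer binds uniquely in its orientation on both templates.
    """
    mode_u = mode.upper().replace("-LIKE", "")
    if mode_u == "TLN1":
        fwd, rev = TLN1_PRIMERS
        skip_amp_len, cass_len = 183, _TLN1_CASSETTE_LEN
    elif mode_u == "CLSTN1":
        fwd, rev = CLSTN1_PRIMERS
        inc_amp_len, cass_len = 278, _CLSTN1_CASSETTE_LEN
        skip_amp_len = inc_amp_len - cass_len
    else:
        raise ValueError(f"unknown fixture mode {mode!r}")

    rev_rc = _revcomp(rev)
    inner_len = skip_amp_len - len(fwd) - len(rev)
    if inner_len < 2:
        raise ValueError("amplicon too short for primer pair")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        inner = _random_seq(rng, inner_len)
        skipping = (_random_seq(rng, flank) + fwd + inner + rev_rc +
                    _random_seq(rng, flank))
        # insert the cassette mid-way through the inter-primer region
        cassette = _random_codons(rng, cass_len // 3)
        if cass_len % 3:
            cassette += _random_seq(rng, cass_len % 3)
        pos = flank + len(fwd) + inner_len // 2
        inclusion = skipping[:pos] + cassette + skipping[pos:]
        if all(_occurs_once(t, fwd) and _occurs_once(t, rev_rc)
               for t in (skipping, inclusion)):
            return PcrFixture(inclusion, skipping, fwd, rev, cassette, pos)
    raise RuntimeError("could not build primer-unique fixture")  # pragma: no cover


# ---------------------------------------------------------------------------
# File emitters
# ---------------------------------------------------------------------------

def write_cohort(table: JunctionTable, annotation: GeneAnnotation,
                 truth: dict, outdir: str | os.PathLike) -> None:
    """Emit SJ.out.tab per sample, merged matrix TSV, GTF and truth JSON."""
    from .junctions import write_sj_tab

    outdir = os.fspath(outdir)
    os.makedirs(os.path.join(outdir, "sj"), exist_ok=True)
    for s in table.samples:
        write_sj_tab(table, s, os.path.join(outdir, "sj", f"{s}.SJ.out.tab"))
    table.to_tsv(os.path.join(outdir, "junction_counts.tsv"))
    annotation.to_gtf(os.path.join(outdir, "annotation.gtf"))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def write_trace(trace: ForceRampTrace, truth: dict, prefix: str | os.PathLike
                ) -> None:
    """Two-column TSV (time_s, height_nm) + JSON sidecar with the schedule."""
    prefix = os.fspath(prefix)
    pd.DataFrame({"time_s": trace.time, "height_nm": trace.height}).to_csv(
        f"{prefix}.tsv", sep="\t", index=False, float_format="%.6f")
    with open(f"{prefix}.json", "w") as fh:
        json.dump({"schedule": {"type": "linear", "f_start_pN": trace.f_start,
                                "loading_rate_pN_s": trace.loading_rate},
                   "truth": truth}, fh, indent=1, sort_keys=True)


def write_pcr_fixture(fix: PcrFixture, prefix: str | os.PathLike,
                      name: str = "fixture") -> None:
    """Templates as FASTA; primers as TSV (name, fwd, rev)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    prefix = os.fspath(prefix)
    records = [
        SeqRecord(Seq(fix.template_inclusion), id=f"{name}_inclusion",
                  description="cassette included"),
        SeqRecord(Seq(fix.template_skipping), id=f"{name}_skipping",
                  description="cassette skipped"),
    ]
    SeqIO.write(records, f"{prefix}.fasta", "fasta")
    pd.DataFrame([{"name": name, "fwd": fix.primer_fwd,
                   "rev": fix.primer_rev}]).to_csv(
        f"{prefix}.primers.tsv", sep="\t", index=False)
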