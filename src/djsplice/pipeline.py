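"""End-to-end synthetic-study pipeline with reproducible provenance.

``run_pipeline`` executes simulate -> annotate -> filter -> DJE ->
events/PSI -> trait association and writes every artifact under one
output directory. Data artifacts are byte-identical across re-runs with
the same config; the wall-clock timestamp lives only in
``provenance.json`` (alongside the package version and a config hash
that is stable under key reordering).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dje import export_spliceplot, filter_junctions, fit_dje, logcpm
from .events import detect_cassette_events, psi_matrix, write_events_bed
from .junctions import annotate_junctions
from .simulate import CohortSpec, simulate_cohort, write_cohort
from .traits import associate, radar_export

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """Configuration schema violation; message lists the offending keys."""


@dataclass
class RunConfig:
    """All stage parameters of the synthetic-study recipe."""

    seed: int = 0
    # cohort
    n_genes: int = 10
    n_samples_per_group: tuple[int, int] = (60, 60)
    junctions_per_gene: int = 6
    cassette_genes: list = field(
        default_factory=lambda: [["gene_1", 0.7, 0.05]])
    gene_abundance: float = 100.0
    nb_dispersion: float = 0.05
    libsize_range: tuple[float, float] = (8e5, 1.2e6)
    # DJE
    min_mean: float = 10.0
    cutoff: float = 1.0
    alpha: float = 0.05
    # events / PSI
    min_cov: float = 10.0
    # traits
    n_traits: int = 3
    trait_coupling: float = -3.0
    trait_noise_sd: float = 0.1
    rho_min: float = 0.2

    _TYPES = {
        "seed": int, "n_genes": int, "junctions_per_gene": int,
        "n_traits": int,
        "gene_abundance": (int, float), "nb_dispersion": (int, float),
        "min_mean": (int, float), "cutoff": (int, float),
        "alpha": (int, float), "min_cov": (int, float),
        "trait_coupling": (int, float), "trait_noise_sd": (int, float),
        "rho_min": (int, float),
        "n_samples_per_group": (list, tuple), "libsize_range": (list, tuple),
        "cassette_genes": (list, tuple),
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(data) - known)
        if bad:
            raise ConfigError(f"unknown config keys: {', '.join(bad)}")
        wrong = sorted(k for k, v in data.items()
                       if k in cls._TYPES and not isinstance(v, cls._TYPES[k]))
        if wrong:
            raise ConfigError(f"wrong type for config keys: {', '.join(wrong)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        self.cohort_spec()  # raises InvalidSpecError on bad values
        bad = [k for k in ("alpha", "rho_min") if not 0 < getattr(self, k) < 1]
        if self.min_mean < 0 or self.min_cov < 0 or self.n_traits < 1:
            bad += ["min_mean/min_cov/n_traits"]
        if bad:
            raise ConfigError(f"invalid values for: {', '.join(bad)}")

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_genes=self.n_genes,
            n_samples_per_group=tuple(self.n_samples_per_group),
            junctions_per_gene=self.junctions_per_gene,
            cassette_genes=[tuple(c) for c in self.cassette_genes],
            gene_abundance=self.gene_abundance,
            nb_dispersion=self.nb_dispersion,
            libsize_range=tuple(self.libsize_range),
            seed=self.seed,
        )

    def to_canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()


def _simulate_traits(cfg: RunConfig, truth: dict) -> pd.DataFrame:
    """Traits x samples: trait_1 is coupled to the first cassette gene's
    per-sample inclusion fraction (AUC-like, negative coupling by
    default); remaining traits are pure noise."""
    rng = np.random.default_rng((cfg.seed + 10_007) % (2 ** 31))
    samples = truth["samples"]
    first_gene = sorted(truth["genes"])[0]
    psi = np.asarray(truth["genes"][first_gene]["psi_per_sample"])
    rows = {"trait_1": cfg.trait_coupling * psi
            + rng.normal(0, cfg.trait_noise_sd, len(samples))}
    for i in range(2, cfg.n_traits + 1):
        rows[f"trait_{i}"] = rng.normal(0, 1.0, len(samples))
    return pd.DataFrame(rows, index=samples).T


def run_pipeline(config: RunConfig, outdir: str | os.PathLike) -> dict:
    """Run the full synthetic-study recipe; returns artifact paths."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name.split(".")[0]] = os.path.join(outdir, name)
        return paths[name.split(".")[0]]

    table, annotation, truth = simulate_cohort(config.cohort_spec())
    write_cohort(table, annotation, truth, outdir)
    paths["counts"] = os.path.join(outdir, "junction_counts.tsv")
    paths["annotation"] = os.path.join(outdir, "annotation.gtf")
    paths["truth"] = os.path.join(outdir, "truth.json")

    statuses = annotate_junctions(table, annotation)
    statuses.to_csv(p("junction_status.tsv"), sep="\t")

    filtered = filter_junctions(table, config.min_mean)
    groups = pd.Series(truth["groups"], index=truth["samples"])
    result = fit_dje(filtered, groups, statuses, cutoff=config.cutoff,
                     alpha=config.alpha)
    result.table.to_csv(p("dje_results.tsv"), sep="\t")

    plots = {gid: export_spliceplot(result, statuses, gid)
             for gid in sorted(truth["genes"])}
    with open(p("spliceplots.json"), "w") as fh:
        json.dump(plots, fh, indent=1, sort_keys=True)

    events = detect_cassette_events(filtered, statuses)
    write_events_bed(events, p("events.tsv"))
    psi = psi_matrix(events, filtered, config.min_cov)
    psi.to_csv(p("psi.tsv"), sep="\t", float_format="%.6f")

    traits = _simulate_traits(config, truth)
    traits.to_csv(p("traits.tsv"), sep="\t", float_format="%.6f")
    features = pd.concat([psi, logcpm(filtered)])
    assoc = associate(features, traits, alpha=config.alpha,
                      rho_min=config.rho_min)
    assoc.to_csv(p("trait_associations.tsv"), sep="\t", index=False,
                 float_format="%.6g")
    with open(p("spliceradar.json"), "w") as fh:
        json.dump(radar_export(assoc, config.alpha, config.rho_min), fh,
                  indent=1, sort_keys=True)

    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump({
            "package": "djsplice",
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "config_hash": config.config_hash,
            "config": dataclasses.asdict(config),
        }, fh, indent=1, sort_keys=True)
    paths["provenance"] = os.path.join(outdir, "provenance.json")
    return paths
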