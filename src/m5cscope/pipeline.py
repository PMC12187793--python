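"""End-to-end pipeline: filter -> geometry -> motifs -> differential
methylation -> expression association -> decay kinetics, driven by a
single configuration, with a JSON manifest recording every artifact and
the exact parameters that produced it.  Reruns with the same inputs and
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import association, decay, diffmeth, filtering, geometry, motifs
from .io_model import (
    ValidationError,
    read_annotation,
    read_ct_table,
    read_expression,
    read_site_table,
    write_table,
)

__all__ = ["Thresholds", "RunConfig", "PipelineError", "run_pipeline", "load_run_config"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class Thresholds:
    """All module thresholds in one place (defaults are the standard
    analysis values)."""

    min_coverage: int = 8
    min_probability: float = 0.9999
    called_probability: float = 0.5
    consensus_delta: float = 0.1
    lfc_cut: float = 1.0
    p_cut: float = 0.001
    eps: float = 0.01
    eps_tpm: float = 0.01
    window_bp: int = 27_000_000
    metagene_bins: int = 90
    junction_proximal: int = 100
    junction_flank_max: int = 400
    motif_pattern: str = "CNGGG"
    top_k: int = 20

    def validate(self) -> None:
        if self.min_coverage < 1:
            raise ValidationError("min_coverage must be >= 1")
        for name in ("min_probability", "called_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.consensus_delta < 0 or self.consensus_delta > 1:
            raise ValidationError("consensus_delta must be in [0, 1]")
        if self.p_cut <= 0 or self.p_cut > 1:
            raise ValidationError("p_cut must be in (0, 1]")
        if self.lfc_cut < 0:
            raise ValidationError("lfc_cut must be >= 0")
        if self.window_bp < 1 or self.metagene_bins < 3 or self.top_k < 1:
            raise ValidationError("window_bp, metagene_bins and top_k must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Inputs and parameters of one pipeline run.

    ``samples`` maps condition name -> {"replicates": [site TSVs],
    "expression": expression TSV (optional)}.  ``comparison`` names the
    (A, B) condition pair for differential analysis.
    """

    samples: Mapping[str, Mapping[str, object]]
    annotation: str
    out_dir: str
    comparison: tuple[str, str] | None = None
    ct_table: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        self.thresholds.validate()
        if not self.samples:
            raise ValidationError("no samples configured")
        for cond, spec in self.samples.items():
            reps = spec.get("replicates", [])
            if not reps:
                raise ValidationError(f"condition {cond!r} has no replicate site tables")
            for p in reps:
                if not Path(p).exists():
                    raise ValidationError(f"site table not found: {p}")
            expr = spec.get("expression")
            if expr and not Path(expr).exists():
                raise ValidationError(f"expression table not found: {expr}")
        if not Path(self.annotation).exists():
            raise ValidationError(f"annotation not found: {self.annotation}")
        if self.ct_table and not Path(self.ct_table).exists():
            raise ValidationError(f"Ct table not found: {self.ct_table}")
        if self.comparison:
            for cond in self.comparison:
                if cond not in self.samples:
                    raise ValidationError(f"comparison condition {cond!r} not in samples")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    thr = Thresholds(**raw.get("thresholds", {}))
    comparison = raw.get("comparison")
    return RunConfig(
        samples=raw["samples"],
        annotation=raw["annotation"],
        out_dir=raw["out_dir"],
        comparison=tuple(comparison) if comparison else None,
        ct_table=raw.get("ct_table"),
        thresholds=thr,
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest.

    Stages: per-condition filtering + replicate consensus; shared-site
    and per-gene summaries; metatranscript/junction/chromosome geometry;
    motif abundance, logo matrix and the pattern-conditioned
    stoichiometry test; differential methylation with top-k extraction;
    methylation-expression association; decay fits and comparisons.  A
    stage failure halts the run with the stage name; artifacts already
    written are preserved.
    """
    config.validate()
    thr = config.thresholds
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(thr),
        "inputs": {
            "annotation": str(config.annotation),
            "ct_table": str(config.ct_table) if config.ct_table else None,
            "samples": {
                cond: {k: (list(map(str, v)) if isinstance(v, list) else str(v))
                       for k, v in spec.items()}
                for cond, spec in config.samples.items()
            },
        },
        "artifacts": {},
        "summary": {},
    }

    def emit(name: str, df, fname: str) -> None:
        path = out / fname
        write_table(df, path)
        manifest["artifacts"][name] = fname

    stage = "load"
    try:
        catalog = read_annotation(config.annotation)
        consensus: dict[str, object] = {}
        funnels = []
        stage = "filter"
        for cond in config.samples:
            reps = []
            for i, p in enumerate(config.samples[cond]["replicates"], 1):
                table = read_site_table(p, sample_id=f"{cond}_rep{i}")
                filtered, funnel = filtering.filter_sites(
                    table, thr.min_coverage, thr.min_probability, thr.called_probability
                )
                funnels.append(
                    {
                        "condition": cond,
                        "replicate": i,
                        "n_tested": funnel.n_tested,
                        "n_called": funnel.n_called,
                        "n_high_confidence": funnel.n_high_confidence,
                        "fraction_high_confidence": funnel.fraction_high_confidence,
                    }
                )
                reps.append(filtered)
            if len(reps) >= 2:
                cons = filtering.replicate_consensus(reps[0], reps[1], thr.consensus_delta)
            else:
                cons = reps[0]
            consensus[cond] = cons
            emit(f"consensus_{cond}", cons, f"consensus_{cond}.tsv")
        emit("funnel", pd.DataFrame(funnels), "funnel.tsv")

        stage = "site_summaries"
        first_cond = next(iter(consensus))
        counts, median_spg = filtering.sites_per_gene(consensus[first_cond], catalog)
        emit("sites_per_gene", counts.reset_index().rename(
            columns={"index": "gene_id"}), "sites_per_gene.tsv")
        manifest["summary"]["median_sites_per_gene"] = median_spg
        if len(consensus) >= 2:
            _, cells = filtering.shared_site_sets(consensus)
            emit(
                "shared_site_sets",
                pd.DataFrame(
                    [{"samples": "&".join(k), "count": v} for k, v in sorted(cells.items())]
                ),
                "shared_site_sets.tsv",
            )

        stage = "geometry"
        ref = consensus[first_cond]
        profile = geometry.metagene_profile(ref, catalog, thr.metagene_bins)
        emit("metagene", profile.to_frame(), "metagene.tsv")
        hist = geometry.junction_distance_histogram(ref, catalog)
        emit("junction_histogram", hist.to_frame(), "junction_histogram.tsv")
        zones = geometry.junction_zone_classification(
            ref, catalog, thr.junction_proximal, thr.junction_flank_max
        )
        emit("junction_zones", zones, "junction_zones.tsv")
        density = geometry.genomic_window_density(ref, catalog, thr.window_bp)
        emit("chromosome_density", density, "chromosome_density.tsv")

        stage = "motifs"
        abundance = motifs.motif_abundance_matrix(consensus)
        emit("motif_abundance", abundance.reset_index(names="sample"), "motif_abundance.tsv")
        pfm = motifs.position_frequency_matrix(ref)
        emit("position_frequencies", pfm.frequencies.reset_index(), "position_frequencies.tsv")

        diff = None
        if config.comparison:
            name_a, name_b = config.comparison
            stage = "motif_test"
            mt = motifs.motif_stoichiometry_test(
                consensus[name_a], consensus[name_b], thr.motif_pattern
            )
            emit("motif_test", pd.DataFrame([dataclasses.asdict(mt)]), "motif_test.tsv")
            manifest["summary"]["motif_test_p"] = mt.pvalue

            stage = "differential_methylation"
            diff = diffmeth.differential_table(
                consensus[name_a], consensus[name_b], name_a, name_b,
                min_cov=thr.min_coverage, lfc_cut=thr.lfc_cut,
                p_cut=thr.p_cut, eps=thr.eps,
            )
            emit("differential", diff.df, "differential.tsv")
            manifest["summary"]["label_counts"] = diff.label_counts()
            hyper, hypo, _flags = diffmeth.top_k_sites(diff, thr.top_k)
            emit("top_hyper", hyper, "top_hyper.tsv")
            emit("top_hypo", hypo, "top_hypo.tsv")

            stage = "expression_association"
            expr_a = config.samples[name_a].get("expression")
            expr_b = config.samples[name_b].get("expression")
            if expr_a and expr_b:
                ea = read_expression(expr_a)
                eb = read_expression(expr_b)
                bins = association.bin_expression_compare(
                    consensus[name_a], consensus[name_b], ea, eb
                )
                emit("expression_bins", bins, "expression_bins.tsv")
                corr = association.methylation_expression_correlation(
                    diff, ea, eb, eps_tpm=thr.eps_tpm
                )
                emit("expression_points", corr.points, "expression_points.tsv")
                summary = pd.DataFrame(
                    [{"r": corr.r, "p": corr.p, "n": corr.n,
                      "n_on_axis": corr.n_on_axis, **corr.quadrants}]
                )
                emit("expression_correlation", summary, "expression_correlation.tsv")
                manifest["summary"]["expression_r"] = corr.r

        stage = "decay"
        if config.ct_table:
            ct = read_ct_table(config.ct_table)
            genes = sorted(ct.df["gene"].unique())
            conditions = sorted(ct.df["condition"].unique())
            fits = []
            for gene in genes:
                for cond in conditions:
                    fit = decay.fit_gene_decay(ct, gene, cond)
                    fits.append(dataclasses.asdict(fit))
            emit("decay_fits", pd.DataFrame(fits), "decay_fits.tsv")
            if config.comparison and all(c in conditions for c in config.comparison):
                comps = [
                    dataclasses.asdict(
                        decay.compare_gene_decay(ct, gene, *config.comparison)
                    )
                    for gene in genes
                ]
                emit("decay_comparisons", pd.DataFrame(comps), "decay_comparisons.tsv")
    except ValidationError as err:
        raise PipelineError(stage, str(err)) from err

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return manifest
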