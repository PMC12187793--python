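"""Seeded synthetic-data generator.

Produces a toy transcriptome (GTF + spliced sequences), per-site m5C call
tables for WT and knockout conditions in two replicates, per-condition
expression tables and a qPCR Ct time course — with the statistical
structure the downstream analysis assumes:

* roughly 1% of tested cytosines carry a prediction probability above
  0.9999 (the high-confidence funnel tier);
* Type I (5'-CNGGG-3') sites draw their stoichiometry from a depleted
  Beta distribution in the knockout (writer-dependent hypomethylation);
* site placement is enriched in the 3'UTR;
* expression change is weakly coupled to methylation change, with a
  configurable target Pearson correlation;
* Ct series follow first-order exponential decay (each transcript
  halving adds one Ct cycle) with condition-specific rates.

Every output derives from its own named child stream of the master seed,
so regenerating one artifact never perturbs another, and identical
configurations yield byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import (
    CtTable,
    ExpressionTable,
    SiteTable,
    TranscriptCatalog,
    TranscriptModel,
    ValidationError,
    write_fasta,
    write_gtf,
    write_table,
)

__all__ = [
    "SimConfig",
    "SimBundle",
    "simulate_transcriptome",
    "simulate_site_universe",
    "simulate_site_calls",
    "couple_expression",
    "simulate_expression",
    "simulate_ct_series",
    "simulate_bundle",
    "write_bundle",
]

LN2 = math.log(2.0)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.  Defaults emulate the study conditions of a
    writer-knockout m5C profiling experiment at desk scale."""

    seed: int = 0
    # transcriptome
    n_genes: int = 150
    p_second_transcript: float = 0.3
    mean_exons: float = 4.0
    exon_len_range: tuple[int, int] = (80, 400)
    intron_len_range: tuple[int, int] = (200, 2000)
    fraction_coding: float = 0.9
    motif_plant_per_kb: float = 3.0      # planted CNGGG occurrences per kb of exon
    n_chromosomes: int = 4
    # site universe
    n_tested_sites: int = 20_000         # tested cytosines shared by both conditions
    high_conf_fraction: float = 0.01     # fraction of tested sites that are real m5C
    type1_enrichment: float = 8.0        # selection weight of CNGGG sites among real
    utr3_weight: float = 4.0             # placement weight of 3'UTR cytosines
    # stoichiometry (Beta with mean m and concentration nu: a=m*nu, b=(1-m)*nu)
    type1_stoich_mean: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.60, "KO": 0.25}
    )
    background_stoich_mean: float = 0.40
    stoich_concentration: float = 10.0
    noise_stoich_beta: tuple[float, float] = (1.0, 3.0)
    # background prediction probabilities: right-skewed so that, together
    # with the real sites, <10% of tested cytosines look "called" (>0.5)
    noise_probability_beta: tuple[float, float] = (0.3, 2.0)
    replicate_stoich_jitter: float = 0.02
    # coverage: negative binomial with this mean and dispersion (shape) n
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    # expression coupling
    expression_target_r: float = 0.263
    expression_noise_sd: float = 0.5
    baseline_log2_tpm_mean: float = 4.0
    baseline_log2_tpm_sd: float = 1.5
    log2fc_eps: float = 0.01
    # decay time course: per-gene per-condition first-order rates (1/h)
    decay_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "ELF3": {"WT": LN2 / 1.5, "KO": LN2 / 1.5},
            "JUNB": {"WT": LN2 / 2.0, "KO": LN2 / 2.0},
            "NTHL1": {"WT": LN2 / 4.0, "KO": LN2 / 3.0},
            "PUS1": {"WT": LN2 / 4.5, "KO": LN2 / 3.5},
            "DYNLL1": {"WT": LN2 / 3.0, "KO": LN2 / 6.0},
            "HYSL1": {"WT": LN2 / 2.5, "KO": LN2 / 5.0},
        }
    )
    timepoints_h: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0)
    n_ct_replicates: int = 3
    ct_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.high_conf_fraction <= 1.0:
            raise ValidationError("high_conf_fraction must be in [0, 1]")
        if not 0.0 <= self.fraction_coding <= 1.0:
            raise ValidationError("fraction_coding must be in [0, 1]")
        for cond, m in self.type1_stoich_mean.items():
            if not 0.0 < m < 1.0:
                raise ValidationError(f"type1 stoichiometry mean for {cond} outside (0, 1)")
        if not -1.0 < self.expression_target_r < 1.0:
            raise ValidationError("expression_target_r must be in (-1, 1)")
        if self.n_genes < 1 or self.n_tested_sites < 1:
            raise ValidationError("n_genes and n_tested_sites must be >= 1")


# named child streams: adding a new output never perturbs existing ones
_STREAMS = {
    "transcriptome": 0,
    "universe": 1,
    "sites_WT": 10,
    "sites_KO": 11,
    "expression": 20,
    "ct": 30,
}


def _stream(config: SimConfig, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[name],))
    )


def _weighted_sample(rng: np.random.Generator, weights: np.ndarray, k: int) -> np.ndarray:
    """k indices sampled without replacement with probability proportional
    to weights (Gumbel top-k)."""
    keys = np.log(weights) + rng.gumbel(size=len(weights))
    idx = np.argpartition(-keys, k - 1)[:k]
    return np.sort(idx)


def simulate_transcriptome(config: SimConfig) -> tuple[TranscriptCatalog, dict[str, str]]:
    """Toy multi-exon transcriptome with planted CNGGG motifs.

    Genes are laid out along a few toy chromosomes; a fraction of genes
    carries a second splice variant that skips one internal exon, so
    variants share genomic exon sequence (exercising genomic
    deduplication downstream).  Returns the catalog and per-transcript
    spliced sequences.
    """
    rng = _stream(config, "transcriptome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursor = {c: 1000 for c in chroms}
    models: dict[str, TranscriptModel] = {}
    sequences: dict[str, str] = {}
    lo_e, hi_e = config.exon_len_range
    lo_i, hi_i = config.intron_len_range
    for i in range(config.n_genes):
        gid = f"G{i:04d}"
        chrom = chroms[i % len(chroms)]
        n_ex = 1 + int(rng.poisson(max(config.mean_exons - 1.0, 0.0)))
        exon_lens = rng.integers(lo_e, hi_e + 1, n_ex)
        intron_lens = rng.integers(lo_i, hi_i + 1, max(n_ex - 1, 0))
        start = cursor[chrom]
        exons: list[tuple[int, int]] = []
        pos = start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < n_ex - 1:
                pos += int(intron_lens[j])
        locus_end = pos
        cursor[chrom] = locus_end + int(rng.integers(5_000, 20_000))
        strand = "+" if rng.random() < 0.5 else "-"
        locus = rng.choice(list("ACGT"), size=locus_end - start)
        # plant CNGGG motifs at exonic offsets
        exonic_len = int(exon_lens.sum())
        n_plant = max(1, int(round(config.motif_plant_per_kb * exonic_len / 1000.0)))
        for _ in range(n_plant):
            ex = exons[int(rng.integers(0, n_ex))]
            if ex[1] - ex[0] < 7:
                continue
            off = int(rng.integers(ex[0] + 1, ex[1] - 6)) - start
            motif = "C" + str(rng.choice(list("ACGT"))) + "GGG"
            if strand == "-":
                motif = _revcomp(motif)
            locus[off : off + 5] = list(motif)
        locus_seq = "".join(locus)

        variants: list[list[tuple[int, int]]] = [exons]
        if n_ex >= 3 and rng.random() < config.p_second_transcript:
            skip = int(rng.integers(1, n_ex - 1))
            variants.append([e for j, e in enumerate(exons) if j != skip])
        for v, v_exons in enumerate(variants):
            tid = f"{gid}T{v + 1}"
            spliced = "".join(locus_seq[s - start : e - start] for s, e in v_exons)
            order = v_exons if strand == "+" else v_exons[::-1]
            seq = spliced if strand == "+" else _revcomp(spliced)
            length = len(seq)
            cds_start = cds_end = None
            if length >= 300 and rng.random() < config.fraction_coding:
                u5 = max(1, int(length * rng.uniform(0.10, 0.20)))
                u3 = max(1, int(length * rng.uniform(0.25, 0.45)))
                if length - u5 - u3 >= 3:
                    cds_start, cds_end = u5, length - u3
            models[tid] = TranscriptModel(
                tid, gid, chrom, strand, tuple(order), cds_start, cds_end
            )
            sequences[tid] = seq
    return TranscriptCatalog(models), sequences


def _is_type1(seq: str, p: int) -> bool:
    return seq[p] == "C" and seq[p + 2 : p + 5] == "GGG"


def simulate_site_universe(
    catalog: TranscriptCatalog, sequences: dict[str, str], config: SimConfig
) -> pd.DataFrame:
    """The fixed set of tested cytosines, shared by both conditions.

    Each tested site carries its 9-mer context and two flags: ``is_real``
    (a genuine m5C site that will receive a high prediction probability)
    and ``is_type1`` (5-mer matches CNGGG).  Real sites are
    3'UTR-enriched and Type-I-enriched per the config weights.
    """
    rng = _stream(config, "universe")
    tids: list[str] = []
    positions: list[int] = []
    kmers: list[str] = []
    type1: list[bool] = []
    utr3: list[bool] = []
    for tid in sorted(catalog.models):
        seq = sequences[tid]
        model = catalog[tid]
        cds_end = model.cds_end_t if model.is_coding else None
        for p in range(4, len(seq) - 4):
            if seq[p] != "C":
                continue
            tids.append(tid)
            positions.append(p)
            kmers.append(seq[p - 4 : p + 5])
            type1.append(_is_type1(seq, p))
            utr3.append(cds_end is not None and p >= cds_end)
    df = pd.DataFrame(
        {
            "transcript_id": tids,
            "position": positions,
            "kmer9": kmers,
            "is_type1": type1,
            "is_utr3": utr3,
        }
    )
    n_tested = min(config.n_tested_sites, len(df))
    w = np.where(df["is_utr3"], config.utr3_weight, 1.0)
    tested_idx = _weighted_sample(rng, w, n_tested)
    df = df.iloc[tested_idx].reset_index(drop=True)
    n_real = int(round(config.high_conf_fraction * len(df)))
    w_real = np.where(df["is_type1"], config.type1_enrichment, 1.0)
    real_idx = _weighted_sample(rng, w_real, n_real) if n_real else np.array([], dtype=int)
    df["is_real"] = False
    df.loc[df.index[real_idx], "is_real"] = True
    return df


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def sample_stoichiometries(
    config: SimConfig,
    condition: str,
    is_type1: bool,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n stoichiometries from the generator's Beta model for real
    sites of the given condition and motif class."""
    mean = (
        config.type1_stoich_mean[condition]
        if is_type1
        else config.background_stoich_mean
    )
    a, b = _beta_params(mean, config.stoich_concentration)
    return rng.beta(a, b, n)


def simulate_site_calls(
    catalog: TranscriptCatalog,
    sequences: dict[str, str],
    config: SimConfig,
    condition: str,
    universe: pd.DataFrame | None = None,
) -> tuple[SiteTable, SiteTable]:
    """Per-site call tables for one condition, two replicates.

    Real sites draw stoichiometry from the condition's Beta (Type I sites
    use the condition-specific, knockout-depleted mean) and a prediction
    probability above 0.9999; the remaining tested sites are background
    noise with low probability.  Replicates share the per-site base
    stoichiometry and probability; stoichiometry is jittered within the
    consensus tolerance and coverage drawn independently per replicate.
    """
    if condition not in config.type1_stoich_mean:
        raise ValidationError(f"no Type I stoichiometry mean configured for {condition!r}")
    if universe is None:
        universe = simulate_site_universe(catalog, sequences, config)
    rng = _stream(config, f"sites_{condition}")
    n = len(universe)
    is_real = universe["is_real"].to_numpy()
    is_type1 = universe["is_type1"].to_numpy()
    nu = config.stoich_concentration
    a1, b1 = _beta_params(config.type1_stoich_mean[condition], nu)
    a0, b0 = _beta_params(config.background_stoich_mean, nu)
    an, bn = config.noise_stoich_beta
    stoich = np.where(
        is_real & is_type1,
        rng.beta(a1, b1, n),
        np.where(is_real, rng.beta(a0, b0, n), rng.beta(an, bn, n)),
    )
    # probability: real sites strictly above 0.9999, noise below it
    u = rng.uniform(4.02, 8.0, n)
    ap, bp = config.noise_probability_beta
    prob = np.where(is_real, 1.0 - 10.0 ** (-u), rng.beta(ap, bp, n) * 0.9999)
    p_nb = config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean)
    tables = []
    for rep in (1, 2):
        jitter = rng.normal(0.0, config.replicate_stoich_jitter, n)
        rep_stoich = np.clip(stoich + jitter, 0.0, 1.0)
        coverage = np.maximum(rng.negative_binomial(config.coverage_dispersion, p_nb, n), 1)
        df = pd.DataFrame(
            {
                "sample_id": f"{condition}_rep{rep}",
                "transcript_id": universe["transcript_id"],
                "position": universe["position"],
                "kmer9": universe["kmer9"],
                "coverage": coverage,
                "stoichiometry": rep_stoich,
                "probability": prob,
            }
        )
        tables.append(
            SiteTable(df.reset_index(drop=True), provenance=(f"simulated {condition} rep{rep}",))
        )
    return tables[0], tables[1]


def couple_expression(
    x: np.ndarray,
    target_r: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Expression log2 fold changes coupled to methylation log2 fold
    changes ``x`` so that the population Pearson correlation equals
    ``target_r``: y = beta * x + N(0, noise_sd) with beta solved from the
    spread of x."""
    x = np.asarray(x, float)
    noise = rng.normal(0.0, noise_sd, len(x))
    sx = float(np.std(x))
    if target_r == 0.0 or sx == 0.0:
        return noise
    beta = noise_sd * target_r / (sx * math.sqrt(1.0 - target_r**2))
    return beta * x + noise


def simulate_expression(
    catalog: TranscriptCatalog,
    site_tables: Mapping[str, SiteTable],
    config: SimConfig,
) -> dict[str, ExpressionTable]:
    """Per-condition TPM tables with methylation-coupled fold changes.

    ``site_tables`` maps condition name -> one replicate's SiteTable.
    Per transcript, the methylation log2FC between the first two
    conditions (mean high-confidence stoichiometry) drives the
    expression log2FC via :func:`couple_expression`; transcripts without
    high-confidence sites in both conditions receive pure noise.  TPMs
    are renormalized to sum to 1e6 per condition.
    """
    rng = _stream(config, "expression")
    conditions = list(site_tables)
    if len(conditions) != 2:
        raise ValidationError("simulate_expression expects exactly 2 conditions")
    tids = sorted(catalog.models)
    mean_stoich: dict[str, pd.Series] = {}
    for cond, table in site_tables.items():
        df = table.df
        high = df[df["probability"] > 0.9999]
        mean_stoich[cond] = high.groupby("transcript_id")["stoichiometry"].mean()
    sa, sb = mean_stoich[conditions[0]], mean_stoich[conditions[1]]
    shared = sa.index.intersection(sb.index)
    eps = config.log2fc_eps
    x = pd.Series(0.0, index=pd.Index(tids))
    x.loc[shared] = np.log2((sa.loc[shared] + eps) / (sb.loc[shared] + eps))
    baseline = rng.normal(config.baseline_log2_tpm_mean, config.baseline_log2_tpm_sd, len(tids))
    y = np.zeros(len(tids))
    sited = x.to_numpy() != 0.0
    y[sited] = couple_expression(
        x.to_numpy()[sited], config.expression_target_r, config.expression_noise_sd, rng
    )
    y[~sited] = rng.normal(0.0, config.expression_noise_sd, int((~sited).sum()))
    # condition A carries baseline + coupled change, condition B the baseline
    tpm = {conditions[0]: 2.0 ** (baseline + y), conditions[1]: 2.0**baseline}
    out: dict[str, ExpressionTable] = {}
    for cond in conditions:
        v = tpm[cond]
        v = v / v.sum() * 1e6
        out[cond] = ExpressionTable(
            pd.DataFrame({"sample_id": cond, "transcript_id": tids, "tpm": v})
        )
    return out


def simulate_ct_series(config: SimConfig) -> CtTable:
    """qPCR Ct time course after transcription shutoff.

    Target Ct rises by k*t/ln2 cycles (one cycle per transcript halving)
    plus Gaussian noise; the reference gene is flat.  Three replicates
    per gene/condition/timepoint by default.
    """
    rng = _stream(config, "ct")
    rows = []
    for gene in config.decay_rates:
        ct0 = float(rng.uniform(18.0, 26.0))
        for condition, k in config.decay_rates[gene].items():
            for t in config.timepoints_h:
                for rep in range(1, config.n_ct_replicates + 1):
                    noise = float(rng.normal(0.0, config.ct_noise_sd)) if config.ct_noise_sd else 0.0
                    rows.append(
                        {
                            "gene": gene,
                            "condition": condition,
                            "timepoint_h": t,
                            "replicate": rep,
                            "ct_target": ct0 + k * t / LN2 + noise,
                            "ct_reference": 20.0,
                        }
                    )
    table = CtTable(pd.DataFrame(rows))
    table.validate()
    return table


@dataclass(frozen=True)
class SimBundle:
    """All artifacts of one simulation run plus the true parameters."""

    config: SimConfig
    catalog: TranscriptCatalog
    sequences: dict[str, str]
    sites: dict[str, tuple[SiteTable, SiteTable]]      # condition -> (rep1, rep2)
    expression: dict[str, ExpressionTable]
    ct: CtTable
    universe: pd.DataFrame


def simulate_bundle(config: SimConfig | None = None) -> SimBundle:
    """Run the full generator under one master seed."""
    config = config or SimConfig()
    catalog, sequences = simulate_transcriptome(config)
    universe = simulate_site_universe(catalog, sequences, config)
    sites = {
        cond: simulate_site_calls(catalog, sequences, config, cond, universe)
        for cond in config.type1_stoich_mean
    }
    first_reps = {cond: reps[0] for cond, reps in sites.items()}
    expression = simulate_expression(catalog, first_reps, config)
    ct = simulate_ct_series(config)
    return SimBundle(config, catalog, sequences, sites, expression, ct, universe)


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> dict[str, str]:
    """Write every artifact of a bundle; returns name -> path manifest.

    Emits the annotation GTF, transcript FASTA, one site TSV per
    condition/replicate, one expression TSV per condition, the Ct table
    and a JSON manifest of the true generator parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        manifest[name] = str(path)

    gtf = out / "annotation.gtf"
    write_gtf(bundle.catalog, gtf)
    emit("annotation", gtf)
    fa = out / "transcripts.fa"
    write_fasta(bundle.sequences, fa)
    emit("sequences", fa)
    for cond in sorted(bundle.sites):
        for i, table in enumerate(bundle.sites[cond], 1):
            p = out / f"sites_{cond}_rep{i}.tsv"
            write_table(table, p)
            emit(f"sites_{cond}_rep{i}", p)
    for cond in sorted(bundle.expression):
        p = out / f"expression_{cond}.tsv"
        write_table(bundle.expression[cond], p)
        emit(f"expression_{cond}", p)
    ctp = out / "ct_table.tsv"
    write_table(bundle.ct, ctp)
    emit("ct_table", ctp)
    truth = asdict(bundle.config)
    truth["type1_stoich_mean"] = dict(truth["type1_stoich_mean"])
    truth["decay_rates"] = {g: dict(v) for g, v in truth["decay_rates"].items()}
    tp = out / "truth.json"
    tp.write_text(json.dumps(truth, indent=2, sort_keys=True, default=list) + "\n")
    emit("truth", tp)
    return manifest
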