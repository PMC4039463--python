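"""End-to-end orchestration: segmentation through survival, plus the
headline-statistic recomputation from the shipped summary tables.

The pipeline consumes marker tracks, expression matrices (tumors and
controls), a gene annotation and a clinical table; stages can be run as a
subset. File-based runs write TSV outputs and a manifest with content
hashes, so identical configurations reproduce identical hashes.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import io as cio
from .genome import GenomeModel
from .segmentation import HMMParams, MarkerTrack, viterbi_segment, \
    filter_cnas, collapse_cn4
from .burden import compute_burden, group_by_burden, map_genes_to_cn, \
    recurrence_counts, DEFAULT_ALTERATION_MIN_LENGTH
from .expression import ControlBaseline, call_matrix, sam_two_class, \
    per_arm_deregulation_test, hierarchical_profile_clustering, to_linear
from .attribution import crosstab_attribution, attribution_from_counts, \
    burden_expression_regression, arm_mlr_decomposition, \
    exclusive_set_analysis, arm_burden_gene_correlation
from .survival import build_cohort, km_estimate, logrank_test, \
    roc_burden_cutoff, spearman_colinearity

STAGES = ("segment", "burden", "express", "attribute", "cluster", "survive")


@dataclass
class PipelineParams:
    """Thresholds shared across stages."""

    min_markers: int = 50
    min_length: int = 500_000
    burden_min_length: int = DEFAULT_ALTERATION_MIN_LENGTH
    genome_size_mb: float | None = None   # None: use the explored genome size
    fc_min: float = 1.5
    alpha: float = 0.05
    recurrence_threshold: int = 4
    sam_permutations: int = 500
    emission_sd: float = 0.25
    self_transition: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_markers", "min_length", "burden_min_length",
                     "fc_min", "alpha", "sam_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineConfig:
    """Declarative file-based run configuration (YAML-loadable)."""

    markers: str
    tumor_expression: str
    control_expression: str
    annotation: str
    clinical: str
    out_dir: str
    germline_cnvs: str | None = None
    expression_scale: str | None = None   # None: trust matrix headers
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)


@dataclass
class PipelineResult:
    segments: pd.DataFrame
    cnas: pd.DataFrame
    burden: pd.DataFrame
    groups: pd.Series
    dosage: pd.DataFrame
    calls: pd.DataFrame
    attribution: object
    regression: object
    mlr: object
    sam_high: object
    sam_low: object
    exclusive: object
    cluster: object | None
    survival: dict


def analyze_cohort(markers: pd.DataFrame, tumor_expr_linear: pd.DataFrame,
                   control_expr_linear: pd.DataFrame, genome: GenomeModel,
                   clinical: pd.DataFrame | None = None,
                   germline_cnvs: pd.DataFrame | None = None,
                   params: PipelineParams | None = None,
                   stages: tuple[str, ...] = STAGES) -> PipelineResult:
    """Run the analysis stages in memory and return all intermediate results."""
    p = params or PipelineParams()
    samples = sorted(markers["sample"].unique())
    hmm = HMMParams(emission_sd=p.emission_sd,
                    self_transition=p.self_transition)

    segments = pd.concat(
        [viterbi_segment(MarkerTrack.from_frame(sub), hmm)
         for _, sub in markers.groupby("sample", sort=True)],
        ignore_index=True)
    cnas = collapse_cn4(filter_cnas(segments, germline_cnvs,
                                    p.min_markers, p.min_length))
    if set(stages) <= {"segment"}:
        return PipelineResult(segments, cnas, *[None] * 12)

    genome_mb = p.genome_size_mb or genome.total_length / 1e6
    burden = compute_burden(cnas, genome, samples, genome_mb,
                            p.burden_min_length)
    groups = group_by_burden(burden)
    dosage = map_genes_to_cn(cnas, genome, samples)
    if set(stages) <= {"segment", "burden"}:
        return PipelineResult(segments, cnas, burden, groups, dosage,
                              *[None] * 8, {})

    tumor_cols = [s for s in tumor_expr_linear.columns if s in samples]
    baseline = ControlBaseline.from_controls(control_expr_linear)
    calls = call_matrix(tumor_expr_linear[tumor_cols], baseline)
    if set(stages) <= {"segment", "burden", "express"}:
        return PipelineResult(segments, cnas, burden, groups, dosage, calls,
                              *[None] * 7, {})

    attribution = crosstab_attribution(dosage[tumor_cols], calls)
    per_tumor = attribution.per_tumor.set_index("sample")
    b = burden.set_index("sample").loc[per_tumor.index]
    regression = burden_expression_regression(b["pct_total"],
                                              per_tumor["ex_total"])
    arm_cols = [f"{a}:altered" for a in genome.arm_ids]
    mlr = arm_mlr_decomposition(
        burden.set_index("sample")[arm_cols].rename(
            columns=lambda c: c.split(":")[0]),
        burden.set_index("sample")["pct_total"])

    high = groups.index[groups == "high"]
    low = groups.index[groups == "low"]
    sam_high = sam_two_class(tumor_expr_linear[list(high)],
                             control_expr_linear, p.fc_min,
                             p.sam_permutations, p.seed)
    sam_low = sam_two_class(tumor_expr_linear[list(low)],
                            control_expr_linear, p.fc_min,
                            p.sam_permutations, p.seed + 1)
    exclusive = exclusive_set_analysis(sam_high, sam_low, dosage, list(high),
                                       p.recurrence_threshold)

    cluster = None
    if "cluster" in stages and exclusive.n_exclusive_high >= 2:
        gene_set = exclusive.exclusive_high_genes
        cluster = hierarchical_profile_clustering(
            np.log2(tumor_expr_linear.loc[gene_set, tumor_cols]), k=2,
            burden_groups=groups, seed=p.seed)

    survival: dict = {}
    if "survive" in stages and clinical is not None:
        cohort = build_cohort(clinical)
        idx = cohort.data["sample"]
        grp = groups.reindex(idx)
        survival["cohort"] = cohort
        survival["km"] = km_estimate(cohort, grp)
        try:
            survival["logrank"] = logrank_test(cohort, grp)
        except ValueError:
            survival["logrank"] = None
        bsub = burden.set_index("sample")["pct_total"].reindex(idx)
        try:
            survival["roc"] = roc_burden_cutoff(bsub.to_numpy(),
                                                cohort.data["event"])
        except ValueError:
            survival["roc"] = None
        survival["spearman"] = spearman_colinearity(
            cohort.data["figo_rank"],
            pd.DataFrame({"pct_cnag": bsub.to_numpy()}))
    return PipelineResult(segments, cnas, burden, groups, dosage, calls,
                          attribution, regression, mlr, sam_high, sam_low,
                          exclusive, cluster, survival)


# ---------------------------------------------------------------------------
# file-based run with manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """File-based run: read inputs, execute the stage subset, write outputs
    and a manifest of parameter and content hashes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": _version, "stages": list(stages),
                      "params": asdict(config.params),
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "inputs": {}, "outputs": {}}
    try:
        markers = cio.read_tsv(config.markers)
        genes = cio.read_bed(config.annotation)
        arms = (markers.groupby("arm")["pos"].max() + 1).astype(int)
        arms = pd.DataFrame({"arm": arms.index,
                             "length": np.maximum(arms.to_numpy(),
                                                  genes.groupby("arm")["end"]
                                                  .max().reindex(arms.index)
                                                  .fillna(0).astype(int))})
        genome = GenomeModel(arms=arms.reset_index(drop=True), genes=genes)
        tumor_expr, scale_t = cio.read_matrix(config.tumor_expression)
        control_expr, scale_c = cio.read_matrix(config.control_expression)
        scale = config.expression_scale or scale_t
        tumor_expr = to_linear(tumor_expr, scale)
        control_expr = to_linear(control_expr, config.expression_scale or scale_c)
        clinical = cio.read_tsv(config.clinical) if config.clinical else None
        germline = (cio.read_bed(config.germline_cnvs).rename(
            columns={"gene_id": "name"})
            if config.germline_cnvs else None)
        for key in ("markers", "tumor_expression", "control_expression",
                    "annotation", "clinical"):
            path = getattr(config, key)
            if path:
                manifest["inputs"][key] = _sha256(Path(path))

        res = analyze_cohort(markers, tumor_expr, control_expr, genome,
                             clinical, germline, config.params, stages)
    except Exception as exc:  # halt with the failing stage named
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        cio.write_tsv(df, path, index=index,
                      comments={"seed": config.params.seed})
        manifest["outputs"][name] = _sha256(path)

    emit("segments.tsv", res.segments)
    emit("cnas.tsv", res.cnas)
    if res.burden is not None:
        emit("burden.tsv", res.burden)
        emit("burden_groups.tsv", res.groups.rename("group").reset_index())
        emit("gene_dosage.tsv", res.dosage, index=True)
        emit("gene_recurrence.tsv", recurrence_counts(res.dosage), index=True)
    if res.calls is not None:
        emit("expression_calls.tsv", res.calls, index=True)
    if res.attribution is not None:
        emit("attribution_per_tumor.tsv", res.attribution.per_tumor)
        summary = pd.DataFrame([{
            "rate_altered": res.attribution.rate_altered,
            "rate_cn2": res.attribution.rate_cn2,
            "dosage_difference": res.attribution.dosage_difference,
            "chi2_p": res.attribution.chi2_p,
            "regression_slope": res.regression.slope,
            "regression_intercept": res.regression.intercept,
            "regression_r": res.regression.r,
            "pct_shared": res.exclusive.pct_shared,
            "pct_exclusive_of_high": res.exclusive.pct_exclusive_of_high,
            "pct_dosage_bound": res.exclusive.pct_dosage_bound,
        }])
        emit("attribution_summary.tsv", summary)
        emit("sam_high.tsv", res.sam_high.stats, index=True)
        emit("sam_low.tsv", res.sam_low.stats, index=True)
    if res.cluster is not None:
        (out / "cluster.nwk").write_text(res.cluster.newick + "\n")
        manifest["outputs"]["cluster.nwk"] = _sha256(out / "cluster.nwk")
        emit("cluster_groups.tsv", res.cluster.groups.reset_index()
             .set_axis(["sample", "cluster"], axis=1))
    if res.survival:
        coh = res.survival["cohort"]
        emit("survival_cohort.tsv", coh.data)
        rows = [{"statistic": "survival_rate_pct", "value": coh.survival_rate},
                {"statistic": "mean_time_to_death", "value": coh.mean_time_to_death}]
        if res.survival.get("logrank"):
            chi2, df_, pval = res.survival["logrank"]
            rows.append({"statistic": "logrank_p", "value": pval})
        if res.survival.get("roc"):
            rows.append({"statistic": "roc_cutoff",
                         "value": res.survival["roc"]["cutoff"]})
        emit("survival_summary.tsv", pd.DataFrame(rows))
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    cio.write_json({k: v for k, v in manifest.items()
                    if k not in ("started", "finished")},
                   out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# headline statistics from the shipped summary tables
# ---------------------------------------------------------------------------

def reproduce_tables(table1: pd.DataFrame, table2: pd.DataFrame,
                     set_counts: dict | None = None,
                     checks: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute the study's headline statistics from the summary tables.

    ``table1`` holds per-tumor burden and status counts, ``table2`` the
    clinical follow-up; ``set_counts`` optionally the SAM set sizes for the
    exclusive-set percentages. Returns a statistic/value report; when
    ``checks`` supplies expected values and tolerances, a pass column is
    added.
    """
    rows: list[tuple[str, float]] = []
    burden = table1.rename(columns={"tumor": "sample",
                                    "pct_genome": "pct_total"})
    rows.append(("mean_pct_cnag", burden["pct_total"].mean()))
    groups = group_by_burden(burden)
    gmeans = burden.set_index("sample")["pct_total"].groupby(groups).mean()
    for g in ("low", "medium", "high"):
        rows.append((f"burden_group_mean_{g}", float(gmeans[g])))
        rows.append((f"burden_group_n_{g}", float((groups == g).sum())))

    from scipy import stats as sps
    r_genes, _ = sps.pearsonr(table1["pct_genome"], table1["genes_cn_altered"])
    rows.append(("genes_vs_burden_pearson_r", float(r_genes)))

    expr = table1.dropna(subset=["all_ex"]).rename(columns={
        "tumor": "sample", "cn13_n": "n_alt", "cn13_ex": "ex_alt",
        "cn2_n": "n_cn2", "cn2_ex": "ex_cn2", "all_ex": "ex_total"})
    att = attribution_from_counts(
        expr[["sample", "n_alt", "ex_alt", "n_cn2", "ex_cn2", "ex_total"]])
    rows += [("rate_cn_altered_pct", att.rate_altered),
             ("rate_cn2_pct", att.rate_cn2),
             ("dosage_difference_pct", att.dosage_difference),
             ("share_deregulated_cn_altered_pct",
              att.share_altered_of_deregulated)]

    reg = burden_expression_regression(expr["pct_genome"], expr["ex_total"])
    rows += [("deregulated_vs_burden_r", reg.r),
             ("deregulated_vs_burden_slope", reg.slope),
             ("deregulated_vs_burden_intercept", reg.intercept)]

    if set_counts is not None:
        from .attribution import exclusive_set_from_counts
        rep = exclusive_set_from_counts(
            set_counts["n_high"], set_counts["n_low"], set_counts["n_common"],
            set_counts["strata"])
        rows += [("pct_shared_low_in_high", rep.pct_shared),
                 ("pct_exclusive_of_high", rep.pct_exclusive_of_high),
                 ("pct_dosage_bound", rep.pct_dosage_bound)]

    cn_clinical = table2[table2["analysis"].str.contains("CN")].copy()
    cohort = build_cohort(cn_clinical)
    rows += [("survival_n", float(cohort.n)),
             ("survival_rate_pct", cohort.survival_rate),
             ("mean_time_to_death_months", cohort.mean_time_to_death)]
    stage_group = cohort.data["stage"].str.replace(
        r"^IV[AB]$", "IV", regex=True)
    for stage, sub in cohort.data.groupby(stage_group):
        rate = 100.0 * (1 - sub["event"].mean())
        rows.append((f"survival_rate_{stage}_pct", float(rate)))

    joined = cohort.data.merge(burden[["sample", "pct_total"]], on="sample")
    if joined["event"].nunique() == 2:
        roc = roc_burden_cutoff(joined["pct_total"], joined["event"])
        rows += [("roc_cutoff_pct", roc["cutoff"]),
                 ("roc_high_n", float(roc["n_high"])),
                 ("roc_high_mean_burden_pct", roc["mean_high"]),
                 ("roc_high_death_rate_pct",
                  100.0 * _death_rate_high(joined, roc["cutoff"]))]

    report = pd.DataFrame(rows, columns=["statistic", "value"])
    if checks is not None and len(checks):
        checks = checks.set_index("statistic")
        report["expected"] = report["statistic"].map(checks["expected"])
        tol = report["statistic"].map(
            checks.get("tol", pd.Series(dtype=float))).fillna(0.05)
        ok = (report["value"] - report["expected"]).abs() <= tol
        report["pass"] = pd.array(
            [bool(o) if pd.notna(e) else None
             for o, e in zip(ok, report["expected"])], dtype="boolean")
    return report


def _death_rate_high(joined: pd.DataFrame, cutoff: float) -> float:
    high = joined[joined["pct_total"] >= cutoff]
    return float(high["event"].mean())
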