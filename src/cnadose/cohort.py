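"""Synthetic tumor cohort generator with planted ground truth.

Emulates the design of a copy-number / expression follow-up study of an
HPV-driven carcinoma cohort: ~31 tumors with a heavily skewed burden
distribution (three strata around 0.5%, 5.4% and 19.2% of the genome
altered), one preferentially amplified arm (the "3q analog") carrying the
majority of gains, 17 normal-epithelium controls, a small planted fraction
of dosage-responsive genes, trans-regulated genes driven by the amplified
arm's burden, and survival / FIGO stage correlated with burden.

Every downstream stage can be validated against the returned
:class:`CohortTruth`. Identical (config, seed) pairs produce byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel, DEFAULT_ARMS, default_genome
from . import io as cio
from .survival import FIGO_ORDER

LOG2_FLOOR = -2.0  # marker log2 ratio emitted for homozygous deletions

#: FIGO stage frequencies used when drawing stages from the burden-linked
#: latent score (advanced-stage-heavy referral population).
FIGO_PROBS = (0.30, 0.15, 0.05, 0.10, 0.30, 0.05, 0.05)


@dataclass
class CohortConfig:
    """Generator settings. Defaults are the desk-scale study conditions:
    a 1/10-scale genome (300 Mb over 8 arms), 2 kb marker spacing, 2,000
    genes, 31 tumors and 17 controls."""

    n_tumors: int = 31
    n_controls: int = 17
    arms: tuple[tuple[str, int], ...] = DEFAULT_ARMS
    marker_spacing: int = 2_000
    n_genes: int = 2000
    gene_length: int = 30_000

    amplified_arm: str = "3q"
    amplified_arm_gain_share: float = 0.55   # share of gained bases on 3q
    gain_fraction: float = 0.66              # gained share of altered bases
    burden_strata_means: tuple[float, ...] = (0.5, 5.4, 19.2)
    burden_strata_sds: tuple[float, ...] = (0.6, 2.4, 6.6)
    min_segment_length: int = 2_600_000
    mean_extra_segment_length: float = 4_000_000.0

    direct_dosage_fraction: float = 0.05
    trans_gene_fraction: float = 0.032
    dosage_effect: float = 3.0               # exponent on (CN/2)
    trans_effect_slope: float = 1.5          # log2 shift per unit 3q gain frac

    marker_noise_sd: float = 0.25
    expr_noise_sd: float = 0.35              # log2-scale residual SD
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5

    survival_beta: float = 0.10              # log-hazard per % burden
    baseline_hazard: float = 0.005           # events per month at 0% burden
    censor_min_months: int = 60
    censor_max_months: int = 86
    other_death_prob: float = 0.03
    untreated_prob: float = 0.10
    figo_weight: float = 0.6                 # burden share of the FIGO latent

    #: explicit planted segments (sample_idx, arm, start, end, cn) override
    #: the burden-driven random planting entirely.
    planted_segments: list[tuple] | None = None

    def __post_init__(self) -> None:
        if self.n_tumors < 3 or self.n_controls < 3:
            raise ValueError("need at least 3 tumors and 3 controls")
        if len(self.arms) < 2:
            raise ValueError("need at least 2 arms")
        if self.marker_spacing <= 0 or self.n_genes < 0:
            raise ValueError("non-positive dimensions")
        if not 0.0 <= self.direct_dosage_fraction <= 1.0:
            raise ValueError("direct_dosage_fraction must lie in [0, 1]")
        if self.amplified_arm not in {a for a, _ in self.arms}:
            raise ValueError("amplified_arm not among arms")


@dataclass
class CohortTruth:
    """Planted ground truth for validating the pipeline."""

    direct_dosage_genes: set[str]
    trans_genes: set[str]
    dosage_effect: float
    trans_effect_slope: float
    true_segments: pd.DataFrame        # sample, arm, start, end, cn
    survival_beta: float
    noise_sd: float
    burden_pct: pd.Series              # true % of explored genome altered
    amplified_arm: str
    amplified_gain_fraction: pd.Series  # gained fraction of the 3q analog


@dataclass
class Cohort:
    genome: GenomeModel
    markers: pd.DataFrame              # sample, arm, pos, log2_ratio
    tumor_expr: pd.DataFrame           # linear intensities, genes x tumors
    control_expr: pd.DataFrame         # linear intensities, genes x controls
    clinical: pd.DataFrame
    truth: CohortTruth
    config: CohortConfig
    seed: int

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.tumor_expr.columns)


# ---------------------------------------------------------------------------
# segment planting
# ---------------------------------------------------------------------------

def _place_segment(free: list[list[int]], length: int,
                   rng: np.random.Generator) -> tuple[int, int] | None:
    """Carve a segment of the given length out of the free-interval list."""
    slots = [i for i, (s, e) in enumerate(free) if e - s >= length]
    if not slots:
        return None
    i = slots[int(rng.integers(len(slots)))]
    s, e = free[i]
    start = int(rng.integers(s, e - length + 1))
    end = start + length
    new = []
    if start - s > 0:
        new.append([s, start])
    if e - end > 0:
        new.append([end, e])
    free[i:i + 1] = new
    return start, end


def _plant_tumor(sample: str, target_pct: float, genome: GenomeModel,
                 cfg: CohortConfig, rng: np.random.Generator) -> list[dict]:
    total_len = genome.total_length
    target_bases = int(round(target_pct / 100.0 * total_len))
    if target_bases < cfg.min_segment_length:
        return []
    free = {arm: [[0, genome.arm_length(arm)]] for arm in genome.arm_ids}
    segments: list[dict] = []

    def add(arm: str, start: int, end: int, gain: bool) -> int:
        if gain:
            cn = 4 if rng.random() < 0.15 else 3
        else:
            cn = 0 if rng.random() < 0.10 else 1
        segments.append({"sample": sample, "arm": arm, "start": start,
                         "end": end, "cn": cn})
        return end - start

    gains_budget = int(round(cfg.gain_fraction * target_bases))
    losses_budget = target_bases - gains_budget

    # the amplified arm takes its share of the gains first, as one block
    amp = cfg.amplified_arm
    amp_len = genome.arm_length(amp)
    amp_target = min(int(round(cfg.amplified_arm_gain_share * gains_budget)),
                     amp_len)
    placed = 0
    if amp_target >= cfg.min_segment_length:
        if amp_target >= 0.85 * amp_len:
            amp_target = amp_len          # snap to a whole-arm gain
        placement = _place_segment(free[amp], amp_target, rng)
        if placement:
            placed += add(amp, *placement, gain=True)
    gains_left = gains_budget - placed

    def fill(budget: int, gain: bool, allowed_arms: list[str]) -> None:
        while budget >= cfg.min_segment_length:
            extra = rng.exponential(cfg.mean_extra_segment_length)
            length = int(cfg.min_segment_length + extra)
            if budget - length < cfg.min_segment_length:
                length = budget           # consume the remainder exactly
            arms = [a for a in allowed_arms
                    if any(e - s >= length for s, e in free[a])]
            if not arms:
                length = cfg.min_segment_length
                arms = [a for a in allowed_arms
                        if any(e - s >= length for s, e in free[a])]
                if not arms:
                    break
            weights = np.array([sum(e - s for s, e in free[a]) for a in arms],
                               dtype=float)
            arm = arms[int(rng.choice(len(arms), p=weights / weights.sum()))]
            placement = _place_segment(free[arm], length, rng)
            if placement is None:
                break
            budget -= add(arm, *placement, gain=gain)

    other_arms = [a for a in genome.arm_ids if a != amp]
    fill(gains_left, True, genome.arm_ids)
    fill(losses_budget, False, other_arms)
    return segments


def _gene_cn_from_truth(genome: GenomeModel, true_segments: pd.DataFrame,
                        samples: list[str]) -> pd.DataFrame:
    """True per-gene copy number (largest-overlap rule) from planted segments."""
    genes = genome.genes
    cn = pd.DataFrame(2, index=genes["gene_id"], columns=samples, dtype=int)
    for seg in true_segments.itertuples(index=False):
        sub = genes[genes["arm"] == seg.arm]
        lo = np.maximum(sub["start"].to_numpy(), seg.start)
        hi = np.minimum(sub["end"].to_numpy(), seg.end)
        hit = hi > lo
        cn.loc[sub.loc[hit, "gene_id"], seg.sample] = seg.cn
    return cn


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Generate the full synthetic study; deterministic in (config, seed)."""
    cfg = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    (s_genome, s_plant, s_markers, s_expr, s_clin) = ss.spawn(5)
    genome = default_genome(cfg.n_genes,
                            seed=int(s_genome.generate_state(1)[0] % 2**31),
                            arms=cfg.arms, gene_length=cfg.gene_length)
    tumor_ids = [f"T{i + 1:03d}" for i in range(cfg.n_tumors)]
    control_ids = [f"C{i + 1:03d}" for i in range(cfg.n_controls)]

    # --- plant copy-number segments --------------------------------------
    rng_p = np.random.default_rng(s_plant)
    seg_rows: list[dict] = []
    if cfg.planted_segments is not None:
        for idx, arm, start, end, cn in cfg.planted_segments:
            seg_rows.append({"sample": tumor_ids[idx], "arm": arm,
                             "start": int(start), "end": int(end),
                             "cn": int(cn)})
    else:
        sizes = _strata_sizes(cfg.n_tumors)
        strata = np.repeat(np.arange(3), sizes)
        for i, t in enumerate(tumor_ids):
            s = strata[i]
            target = max(0.0, rng_p.normal(cfg.burden_strata_means[s],
                                           cfg.burden_strata_sds[s]))
            seg_rows.extend(_plant_tumor(t, target, genome, cfg, rng_p))
    true_segments = pd.DataFrame(
        seg_rows, columns=["sample", "arm", "start", "end", "cn"])

    seg_len = (true_segments["end"] - true_segments["start"])
    burden = (true_segments.assign(length=seg_len)
              .groupby("sample")["length"].sum()
              .reindex(tumor_ids, fill_value=0) / genome.total_length * 100.0)
    burden.name = "burden_pct"
    amp_len = genome.arm_length(cfg.amplified_arm)
    amp_gain = (true_segments[(true_segments["arm"] == cfg.amplified_arm)
                              & (true_segments["cn"] > 2)]
                .assign(length=lambda d: d["end"] - d["start"])
                .groupby("sample")["length"].sum()
                .reindex(tumor_ids, fill_value=0) / amp_len)
    amp_gain.name = "amplified_gain_fraction"

    # --- marker tracks -----------------------------------------------------
    rng_m = np.random.default_rng(s_markers)
    marker_frames = []
    for t in tumor_ids:
        segs_t = true_segments[true_segments["sample"] == t]
        for arm in genome.arm_ids:
            length = genome.arm_length(arm)
            pos = np.arange(cfg.marker_spacing // 2, length, cfg.marker_spacing)
            cn = np.full(len(pos), 2, dtype=int)
            for seg in segs_t[segs_t["arm"] == arm].itertuples(index=False):
                cn[(pos >= seg.start) & (pos < seg.end)] = seg.cn
            mean = np.where(cn == 0, LOG2_FLOOR, np.log2(np.maximum(cn, 1) / 2.0))
            lr = mean + rng_m.normal(0.0, cfg.marker_noise_sd, size=len(pos))
            marker_frames.append(pd.DataFrame({
                "sample": t, "arm": arm, "pos": pos, "log2_ratio": lr}))
    markers = pd.concat(marker_frames, ignore_index=True)

    # --- expression --------------------------------------------------------
    rng_e = np.random.default_rng(s_expr)
    gene_ids = genome.genes["gene_id"].to_numpy()
    n_genes = len(gene_ids)
    mu = rng_e.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n_genes)

    n_direct = int(round(cfg.direct_dosage_fraction * n_genes))
    direct_genes = set(rng_e.choice(gene_ids, size=n_direct, replace=False))
    non_amp = genome.genes.loc[genome.genes["arm"] != cfg.amplified_arm,
                               "gene_id"].to_numpy()
    n_trans = int(round(cfg.trans_gene_fraction * n_genes))
    trans_genes = set(rng_e.choice(non_amp, size=min(n_trans, len(non_amp)),
                                   replace=False))

    control_log2 = (mu[:, None]
                    + rng_e.normal(0.0, cfg.expr_noise_sd,
                                   (n_genes, cfg.n_controls)))
    tumor_log2 = (mu[:, None]
                  + rng_e.normal(0.0, cfg.expr_noise_sd,
                                 (n_genes, cfg.n_tumors)))
    true_cn = _gene_cn_from_truth(genome, true_segments, tumor_ids)
    is_direct = np.isin(gene_ids, list(direct_genes))
    cn_arr = true_cn.to_numpy()
    dosage_log2 = np.where(cn_arr == 0, LOG2_FLOOR,
                           np.log2(np.maximum(cn_arr, 1) / 2.0))
    tumor_log2 += cfg.dosage_effect * dosage_log2 * is_direct[:, None]
    is_trans = np.isin(gene_ids, list(trans_genes))
    tumor_log2 += (cfg.trans_effect_slope
                   * amp_gain.to_numpy()[None, :] * is_trans[:, None])

    tumor_expr = pd.DataFrame(2.0 ** tumor_log2, index=gene_ids,
                              columns=tumor_ids).rename_axis("gene_id")
    control_expr = pd.DataFrame(2.0 ** control_log2, index=gene_ids,
                                columns=control_ids).rename_axis("gene_id")

    # --- clinical ----------------------------------------------------------
    rng_c = np.random.default_rng(s_clin)
    hazard = cfg.baseline_hazard * np.exp(cfg.survival_beta * burden.to_numpy())
    t_death = rng_c.exponential(1.0 / hazard)
    censor = rng_c.uniform(cfg.censor_min_months, cfg.censor_max_months,
                           cfg.n_tumors)
    other = rng_c.random(cfg.n_tumors) < cfg.other_death_prob
    t_other = rng_c.uniform(1.0, censor)
    followup = np.minimum(np.minimum(t_death, censor),
                          np.where(other, t_other, np.inf))
    status = np.where(followup == censor, "alive",
                      np.where(other & (t_other <= t_death), "censored-death",
                               "death"))
    followup_months = np.maximum(1, np.round(followup)).astype(int)
    treated = rng_c.random(cfg.n_tumors) >= cfg.untreated_prob

    w = cfg.figo_weight
    z_burden = (burden - burden.mean()) / (burden.std(ddof=0) or 1.0)
    latent = w * z_burden.to_numpy() + np.sqrt(1 - w ** 2) * rng_c.normal(
        size=cfg.n_tumors)
    order = np.argsort(np.argsort(latent, kind="stable"), kind="stable")
    cuts = np.cumsum(np.round(np.array(FIGO_PROBS) * cfg.n_tumors)).astype(int)
    cuts[-1] = cfg.n_tumors
    stage_idx = np.searchsorted(cuts, order, side="right")
    stages = np.array(FIGO_ORDER)[np.clip(stage_idx, 0, len(FIGO_ORDER) - 1)]

    clinical = pd.DataFrame({
        "sample": tumor_ids,
        "stage": stages,
        "followup_months": followup_months,
        "status": status,
        "treated": treated,
    })

    truth = CohortTruth(
        direct_dosage_genes=direct_genes, trans_genes=trans_genes,
        dosage_effect=cfg.dosage_effect,
        trans_effect_slope=cfg.trans_effect_slope,
        true_segments=true_segments, survival_beta=cfg.survival_beta,
        noise_sd=cfg.expr_noise_sd, burden_pct=burden,
        amplified_arm=cfg.amplified_arm, amplified_gain_fraction=amp_gain)
    return Cohort(genome=genome, markers=markers, tumor_expr=tumor_expr,
                  control_expr=control_expr, clinical=clinical, truth=truth,
                  config=cfg, seed=seed)


def _strata_sizes(n: int) -> list[int]:
    base, rem = divmod(n, 3)
    return [base + (1 if i < rem else 0) for i in range(3)]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort to TSV/BED files; round-trips bit-exactly through
    the readers in :mod:`cnadose.io`."""
    out = Path(out_dir)
    seed = cohort.seed
    files = {
        "markers": out / "markers.tsv",
        "tumor_expr": out / "tumor_expression.tsv",
        "control_expr": out / "control_expression.tsv",
        "genes": out / "genes.bed",
        "clinical": out / "clinical.tsv",
        "truth_segments": out / "truth_segments.tsv",
        "truth_genes": out / "truth_genes.tsv",
    }
    cio.write_tsv(cohort.markers, files["markers"], comments={"seed": seed})
    cio.write_matrix(cohort.tumor_expr, files["tumor_expr"], "linear", seed)
    cio.write_matrix(cohort.control_expr, files["control_expr"], "linear", seed)
    cio.write_bed(cohort.genome.genes, files["genes"], seed)
    cio.write_tsv(cohort.clinical, files["clinical"], comments={"seed": seed})
    cio.write_tsv(cohort.truth.true_segments, files["truth_segments"],
                  comments={"seed": seed})
    genes = cohort.genome.genes["gene_id"]
    truth_genes = pd.DataFrame({
        "gene_id": genes,
        "direct_dosage": genes.isin(cohort.truth.direct_dosage_genes).to_numpy(),
        "trans": genes.isin(cohort.truth.trans_genes).to_numpy(),
    })
    cio.write_tsv(truth_genes, files["truth_genes"], comments={"seed": seed})
    return files
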