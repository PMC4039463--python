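"""Per-tumor copy-number burden and gene-level dosage status.

Burden is expressed as %CN-AG: the fraction of the haploid genome inside
copy-number alterations larger than a size threshold (2.5 Mb by default).
Tumors are stratified into low/medium/high burden groups; genes receive a
per-tumor dosage status CN1 (one copy lost), CN2 (diploid) or CN3 (three or
four copies) from interval overlap with the filtered CNAs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeModel, HAPLOID_GENOME_MB

GAIN_STATES = (3, 4)
LOSS_STATES = (0, 1)

#: Size threshold above which a segment counts toward burden (strict >).
DEFAULT_ALTERATION_MIN_LENGTH = 2_500_000

BURDEN_GROUPS = ("low", "medium", "high")


def _check_no_conflicting_overlap(cnas: pd.DataFrame) -> None:
    for (sample, arm), sub in cnas.groupby(["sample", "arm"]):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        states = sub["state"].to_numpy()
        bad = (starts[1:] < ends[:-1]) & (states[1:] != states[:-1])
        if bad.any():
            raise ValueError(
                f"overlapping segments of different states in {sample}/{arm}")


def compute_burden(cnas: pd.DataFrame, genome: GenomeModel | None = None,
                   samples: list[str] | None = None,
                   genome_size_mb: float = HAPLOID_GENOME_MB,
                   alteration_min_length: int = DEFAULT_ALTERATION_MIN_LENGTH,
                   ) -> pd.DataFrame:
    """Per-tumor burden statistics (%CN-AG, gained/deleted split, per arm).

    Only segments strictly longer than ``alteration_min_length`` enter the
    percentages. The genome-wide denominator is ``genome_size_mb`` (3,000 Mb
    by convention); per-arm percentages use the arm lengths of ``genome``.
    Returns one row per sample with columns ``pct_total``, ``pct_gained``,
    ``pct_deleted``, ``n_cnas`` and, when a genome is given, per-arm columns
    ``{arm}:altered/gained/deleted``.
    """
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    _check_no_conflicting_overlap(cnas)
    if samples is None:
        samples = sorted(cnas["sample"].unique())
    big = cnas[cnas["length"] > alteration_min_length]
    denom = genome_size_mb * 1e6
    rows = []
    for sample in samples:
        sub = big[big["sample"] == sample]
        gained = sub[sub["state"].isin(GAIN_STATES)]["length"].sum()
        deleted = sub[sub["state"].isin(LOSS_STATES)]["length"].sum()
        row = {
            "sample": sample,
            "pct_total": 100.0 * (gained + deleted) / denom,
            "pct_gained": 100.0 * gained / denom,
            "pct_deleted": 100.0 * deleted / denom,
            "n_cnas": int(len(sub)),
        }
        if genome is not None:
            for arm in genome.arm_ids:
                armsub = sub[sub["arm"] == arm]
                alen = genome.arm_length(arm)
                g = armsub[armsub["state"].isin(GAIN_STATES)]["length"].sum()
                d = armsub[armsub["state"].isin(LOSS_STATES)]["length"].sum()
                row[f"{arm}:altered"] = 100.0 * (g + d) / alen
                row[f"{arm}:gained"] = 100.0 * g / alen
                row[f"{arm}:deleted"] = 100.0 * d / alen
        rows.append(row)
    return pd.DataFrame(rows)


def group_sizes(n: int, k: int = 3) -> list[int]:
    """Group sizes with the remainder assigned to the earliest groups
    (n=31 -> [11, 10, 10], the low group absorbing the extra tumor)."""
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def group_by_burden(burdens: pd.DataFrame,
                    sizes: list[int] | None = None) -> pd.Series:
    """Assign each tumor to a low/medium/high burden group.

    Tumors are sorted ascending by ``pct_total`` (ties broken by sample id)
    and split into three consecutive blocks. Returns sample -> group label.
    """
    n = len(burdens)
    if n < 3:
        raise ValueError("need at least 3 tumors to form groups")
    if sizes is None:
        sizes = group_sizes(n)
    if sum(sizes) != n or len(sizes) != 3:
        raise ValueError("sizes must be three counts summing to the cohort size")
    ordered = burdens.sort_values(["pct_total", "sample"])["sample"].to_numpy()
    labels = np.repeat(BURDEN_GROUPS, sizes)
    return pd.Series(labels, index=ordered, name="burden_group").rename_axis("sample")


def map_genes_to_cn(cnas: pd.DataFrame, genome: GenomeModel,
                    samples: list[str] | None = None) -> pd.DataFrame:
    """Per-gene, per-tumor dosage status from interval overlap.

    Any overlap (>= 1 bp) with a loss CNA gives CN1, with a gain CNA CN3;
    genes overlapping neither stay CN2. A gene hit by both a gain and a loss
    in the same tumor takes the status with the larger base overlap, ties
    going to the gain. Returns a genes x samples frame of values {1, 2, 3}.
    """
    if samples is None:
        samples = sorted(cnas["sample"].unique())
    genes = genome.genes
    lengths = genome.arms.set_index("arm")["length"]
    if len(genes):
        out_of_bounds = (genes["end"].to_numpy() >
                         lengths.loc[genes["arm"]].to_numpy())
        if out_of_bounds.any() or (genes["start"] < 0).any():
            raise ValueError("gene outside genome bounds")
    status = pd.DataFrame(2, index=genes["gene_id"], columns=samples, dtype=int)
    by_arm = {arm: sub.reset_index(drop=True) for arm, sub in genes.groupby("arm")}
    for sample in samples:
        seg_s = cnas[cnas["sample"] == sample]
        gain_ov = pd.Series(0, index=genes["gene_id"], dtype=np.int64)
        loss_ov = pd.Series(0, index=genes["gene_id"], dtype=np.int64)
        for seg in seg_s.itertuples(index=False):
            arm_genes = by_arm.get(seg.arm)
            if arm_genes is None or seg.state == 2:
                continue
            lo = np.minimum(np.maximum(arm_genes["start"].to_numpy(), seg.start),
                            seg.end)
            hi = np.minimum(arm_genes["end"].to_numpy(), seg.end)
            ov = np.maximum(hi - lo, 0)
            hit = ov > 0
            ids = arm_genes.loc[hit, "gene_id"]
            if seg.state in GAIN_STATES:
                gain_ov.loc[ids] += ov[hit]
            else:
                loss_ov.loc[ids] += ov[hit]
        status[sample] = np.where(
            (gain_ov == 0) & (loss_ov == 0), 2,
            np.where(gain_ov >= loss_ov, 3, 1))
    return status


def recurrence_counts(dosage: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of tumors with a gain, a loss, or any alteration."""
    return pd.DataFrame({
        "n_gained": (dosage == 3).sum(axis=1),
        "n_deleted": (dosage == 1).sum(axis=1),
        "n_altered": (dosage != 2).sum(axis=1),
    })


def recurrence_curve(dosage: pd.DataFrame, direction: str = "combined",
                     gene_subset: list[str] | None = None) -> pd.DataFrame:
    """Accumulated recurrence of altered genes.

    For k = 1..n_tumors, the fraction of ever-altered genes that are altered
    in at least k tumors (monotone non-increasing, 1 at k = 1). ``direction``
    selects gains, losses or any alteration; ``gene_subset`` restricts the
    gene universe (e.g. one arm's genes).
    """
    if len(dosage) == 0:
        raise ValueError("empty dosage table")
    sub = dosage.loc[gene_subset] if gene_subset is not None else dosage
    if direction == "gained":
        counts = (sub == 3).sum(axis=1)
    elif direction == "deleted":
        counts = (sub == 1).sum(axis=1)
    elif direction == "combined":
        counts = (sub != 2).sum(axis=1)
    else:
        raise ValueError("direction must be gained, deleted or combined")
    n_tumors = dosage.shape[1]
    ever = int((counts >= 1).sum())
    ks = np.arange(1, n_tumors + 1)
    if ever == 0:
        frac = np.zeros(n_tumors)
    else:
        frac = np.array([(counts >= k).sum() / ever for k in ks])
    return pd.DataFrame({"k": ks, "fraction": frac})
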