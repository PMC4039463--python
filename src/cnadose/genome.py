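"""Genome model: chromosome arms and gene annotation.

All coordinates are 0-based, half-open intervals in base pairs. The model is
deliberately minimal: a list of arms with lengths, and non-overlapping gene
intervals assigned to arms. The default synthetic genome is a 1/10-scale
stand-in for the human genome (300 Mb over 8 arms) so that desk-scale runs
exercise the same arithmetic as a full 3,000 Mb analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Denominator used for genome-wide burden percentages, in Mb. The haploid
#: human genome is taken as 3,000 Mb by convention; synthetic genomes pass
#: their own explored size instead.
HAPLOID_GENOME_MB = 3000.0


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome arms plus a gene annotation table.

    Parameters
    ----------
    arms : pd.DataFrame
        Columns ``arm`` (str) and ``length`` (int, bp), one row per arm.
    genes : pd.DataFrame
        Columns ``gene_id``, ``arm``, ``start``, ``end`` (0-based half-open).
    """

    arms: pd.DataFrame
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "arm", "start", "end"]))

    def __post_init__(self) -> None:
        arms = self.arms
        if arms["arm"].duplicated().any():
            raise ValueError("duplicate arm ids")
        if (arms["length"] <= 0).any():
            raise ValueError("arm lengths must be positive")
        genes = self.genes
        if len(genes):
            if genes["gene_id"].duplicated().any():
                raise ValueError("duplicate gene ids")
            lengths = arms.set_index("arm")["length"]
            unknown = set(genes["arm"]) - set(lengths.index)
            if unknown:
                raise ValueError(f"genes on unknown arms: {sorted(unknown)}")
            if (genes["start"] < 0).any() or (genes["end"] <= genes["start"]).any():
                raise ValueError("gene intervals must be non-empty and non-negative")
            if (genes["end"].to_numpy() >
                    lengths.loc[genes["arm"]].to_numpy()).any():
                raise ValueError("gene extends past its arm")
            for _, sub in genes.groupby("arm"):
                s = sub.sort_values("start")
                if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                    raise ValueError("overlapping genes within an arm")

    @property
    def arm_ids(self) -> list[str]:
        return list(self.arms["arm"])

    def arm_length(self, arm: str) -> int:
        return int(self.arms.set_index("arm").loc[arm, "length"])

    @property
    def total_length(self) -> int:
        return int(self.arms["length"].sum())

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_arm_map(self) -> pd.Series:
        """gene_id -> arm."""
        return self.genes.set_index("gene_id")["arm"]


#: Default synthetic arm layout: 8 arms, 300 Mb total. ``3q`` is the
#: preferentially amplified arm in the cohort generator.
DEFAULT_ARMS = (
    ("1p", 50_000_000),
    ("1q", 45_000_000),
    ("2p", 40_000_000),
    ("2q", 40_000_000),
    ("3p", 35_000_000),
    ("3q", 45_000_000),
    ("4p", 20_000_000),
    ("4q", 25_000_000),
)


def default_genome(n_genes: int = 2000, seed: int = 0,
                   arms: tuple[tuple[str, int], ...] = DEFAULT_ARMS,
                   gene_length: int = 30_000) -> GenomeModel:
    """Build the default synthetic genome with evenly spread genes.

    Genes are placed on a regular grid per arm (counts proportional to arm
    length), so they are non-overlapping by construction; ``seed`` jitters
    the gene starts within their grid cells.
    """
    rng = np.random.default_rng(seed)
    arms_df = pd.DataFrame(arms, columns=["arm", "length"])
    if n_genes == 0:
        return GenomeModel(arms=arms_df)
    total = arms_df["length"].sum()
    rows = []
    idx = 0
    for arm, length in arms:
        n_arm = max(1, int(round(n_genes * length / total)))
        cell = length // n_arm
        if cell <= gene_length:
            raise ValueError("too many genes for arm length")
        offsets = rng.integers(0, cell - gene_length, size=n_arm)
        for k in range(n_arm):
            start = int(k * cell + offsets[k])
            rows.append((f"G{idx:05d}", arm, start, start + gene_length))
            idx += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "arm", "start", "end"])
    return GenomeModel(arms=arms_df, genes=genes)
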