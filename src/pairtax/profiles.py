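"""Relative-abundance profiles and the weighted-difference divergence.

A profile is a per-sample composition over taxonomic labels at one rank.
Two profiles x and y are compared taxon by taxon: the difference in
abundance dif_i = x_i − y_i is multiplied by a weighting factor
w_i = (x_i − y_i) / ((x_i + y_i)/2), giving a contribution
(x_i − y_i)² / ((x_i + y_i)/2) that accounts for relative as well as
absolute change — a 1-point absolute shift matters far more for a taxon
expected at 0.5% (a 200% relative change) than for one at 5% (20%).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .otu import SampleOTUTable
from .taxonomy import RANKS, Assignment

UNASSIGNED = "unassigned"


@dataclass
class Profile:
    sample_id: str
    rank: str
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("negative abundance")
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile mass {total} != 1")


@dataclass
class WeightedDifference:
    total: float
    per_taxon: dict[str, float]


def make_profile(
    table: SampleOTUTable,
    assignments: Sequence[Assignment],
    rank: str = "genus",
    use_rescued: bool = True,
) -> Profile:
    """Aggregate a sample's OTU masses onto labels at ``rank``.

    Chimera-flagged OTUs are excluded; an OTU whose assignment is
    shallower than ``rank`` contributes to a reserved "unassigned" label
    so that mass is conserved.
    """
    idx = RANKS.index(rank)
    by_id = {a.otu_id: a for a in assignments}
    masses: dict[str, float] = {}
    total = 0.0
    for rec in table.non_chimeric():
        a = by_id.get(rec.otu_id)
        if a is None:
            raise ValueError(f"no assignment for OTU {rec.otu_id}")
        mass = rec.count + (rec.rescued if use_rescued else 0)
        label = a.lineage[idx] or UNASSIGNED
        masses[label] = masses.get(label, 0.0) + mass
        total += mass
    if total == 0:
        raise ValueError(f"sample {table.sample_id} has no non-chimeric OTU mass")
    return Profile(
        sample_id=table.sample_id,
        rank=rank,
        abundances={k: v / total for k, v in masses.items()},
    )


def profile_from_fractions(
    sample_id: str, rank: str, fractions: Mapping[str, float]
) -> Profile:
    """Profile straight from label → fraction (e.g. an expected design)."""
    return Profile(sample_id=sample_id, rank=rank, abundances=dict(fractions))


def relative_change(abs_change: float, expected: float) -> float:
    """Absolute change in percentage points as a percentage of the
    expected abundance: relative_change(1, 0.5) = 200."""
    if expected <= 0:
        raise ValueError("expected abundance must be positive")
    return 100.0 * abs_change / expected


def weighted_difference(x: Profile, y: Profile) -> WeightedDifference:
    """Sum over taxa of (x_i − y_i)² / ((x_i + y_i)/2).

    Labels are taken over the union of both supports with missing values
    read as 0; taxa absent from both contribute nothing.  Symmetric,
    non-negative, zero exactly when the profiles agree (a divergence —
    no triangle inequality is claimed).
    """
    if x.rank != y.rank:
        raise ValueError(f"rank mismatch: {x.rank} vs {y.rank}")
    per_taxon: dict[str, float] = {}
    for label in sorted(set(x.abundances) | set(y.abundances)):
        xi = x.abundances.get(label, 0.0)
        yi = y.abundances.get(label, 0.0)
        if xi + yi == 0:
            continue
        per_taxon[label] = (xi - yi) ** 2 / ((xi + yi) / 2.0)
    return WeightedDifference(total=sum(per_taxon.values()), per_taxon=per_taxon)


def profile_matrix(profiles: Sequence[Profile]) -> pd.DataFrame:
    """Taxa × samples relative-abundance matrix (missing = 0)."""
    return (
        pd.DataFrame(
            {p.sample_id: pd.Series(p.abundances) for p in profiles}
        )
        .fillna(0.0)
        .sort_index()
    )


def distance_matrix(profiles: Sequence[Profile]) -> pd.DataFrame:
    """Pairwise weighted-difference matrix across samples."""
    n = len(profiles)
    ids = [p.sample_id for p in profiles]
    mat = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = weighted_difference(profiles[i], profiles[j]).total
            mat[i][j] = mat[j][i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def write_profiles(
    profiles: Sequence[Profile], out_dir: str | Path, prefix: str = "profile"
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profile_matrix(profiles).to_csv(out_dir / f"{prefix}_matrix.tsv", sep="\t")
    distance_matrix(profiles).to_csv(out_dir / f"{prefix}_distances.tsv", sep="\t")
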