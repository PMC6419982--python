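"""Per-sample OTU picking from trimmed read pairs.

An OTU here is a unique (5' read, 3' read) sequence pair within one
sample — no clustering radius is applied.  Picking is a per-sample
minimum relative-abundance filter (default 0.1%): rare unique pairs are
overwhelmingly PCR/sequencing artifacts, and filtering per sample rather
than over the pooled dataset keeps the cutoff meaningful under unequal
sample sizes.  Two corrections follow:

* **rescue** — error is sequence-specific, so an abundance filter alone
  biases against error-prone amplicons; reads discarded by the filter
  are therefore re-assigned to an accepted OTU at a single mismatch
  (Hamming distance 1 over the concatenated pair) and tallied
  separately, never altering acceptance itself;
* **chimera flagging** — a de-novo parent-based rule: OTU C is flagged
  when some accepted A shares its 5' read, some accepted B shares its 3'
  read, and both A and B are at least ``fold`` (default 2) times as
  abundant as C.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .demux import TrimmedPair

PairKey = tuple[str, str]  # (fwd, rev) sequences


@dataclass
class OTURecord:
    otu_id: str
    fwd: str
    rev: str
    count: int
    rescued: int = 0
    chimera: bool = False

    @property
    def key(self) -> PairKey:
        return (self.fwd, self.rev)


@dataclass
class SampleOTUTable:
    sample_id: str
    total_reads: int
    records: list[OTURecord]
    threshold: float

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def non_chimeric(self) -> list[OTURecord]:
        return [r for r in self.records if not r.chimera]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "otu_id": r.otu_id,
                    "fwd": r.fwd,
                    "rev": r.rev,
                    "count": r.count,
                    "rescued": r.rescued,
                    "chimera": r.chimera,
                }
                for r in self.records
            ],
            columns=["otu_id", "fwd", "rev", "count", "rescued", "chimera"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_fasta(self, path: str | Path, separator: str = ".") -> None:
        """FASTA of OTU sequences as ``fwd<separator>rev`` single records."""
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.otu_id}\n{r.fwd}{separator}{r.rev}\n")


def read_otu_table(path: str | Path, sample_id: str | None = None,
                   threshold: float = 0.001) -> SampleOTUTable:
    df = pd.read_csv(path, sep="\t", dtype={"fwd": str, "rev": str})
    records = [
        OTURecord(
            otu_id=str(row.otu_id),
            fwd=row.fwd,
            rev=row.rev,
            count=int(row.count),
            rescued=int(row.rescued),
            chimera=bool(row.chimera),
        )
        for row in df.itertuples(index=False)
    ]
    total = int(sum(r.count + r.rescued for r in records))
    return SampleOTUTable(
        sample_id=sample_id or Path(path).stem,
        total_reads=total,
        records=records,
        threshold=threshold,
    )


def dereplicate(pairs: Iterable[TrimmedPair]) -> Counter[PairKey]:
    """Counts of exactly identical (fwd, rev) pairs; Σcounts == n input."""
    return Counter((p.fwd, p.rev) for p in pairs)


def pick_otus(
    derep: Mapping[PairKey, int],
    total_reads: int,
    threshold: float = 0.001,
    sample_id: str = "sample",
) -> tuple[SampleOTUTable, Counter[PairKey]]:
    """Split dereplicated pairs into accepted OTUs and a discarded multiset.

    A pair is accepted iff count / total_reads >= threshold.  Accepted
    records are ordered by descending count, ties broken lexicographically
    on (fwd, rev), and named ``<sample_id>_OTU<rank>``.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    if total_reads != sum(derep.values()):
        raise ValueError("total_reads does not equal the dereplicated count sum")
    if total_reads == 0:
        return (
            SampleOTUTable(sample_id, 0, [], threshold),
            Counter(),
        )
    accepted_keys = [
        k for k, c in derep.items() if c / total_reads >= threshold
    ]
    accepted_keys.sort(key=lambda k: (-derep[k], k))
    records = [
        OTURecord(otu_id=f"{sample_id}_OTU{i + 1}", fwd=k[0], rev=k[1], count=derep[k])
        for i, k in enumerate(accepted_keys)
    ]
    discarded = Counter(
        {k: c for k, c in derep.items() if c / total_reads < threshold}
    )
    table = SampleOTUTable(sample_id, total_reads, records, threshold)
    return table, discarded


def _hamming_le(a: str, b: str, limit: int) -> int | None:
    """Hamming distance of equal-length strings if <= limit, else None."""
    if len(a) != len(b):
        return None
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return None
    return d


def rescue_discarded(
    table: SampleOTUTable, discarded: Mapping[PairKey, int]
) -> tuple[SampleOTUTable, Counter[PairKey]]:
    """Credit discarded unique pairs within one mismatch of an accepted OTU.

    Distance is Hamming over the fwd+rev concatenation: one substitution
    total across both mates.  A pair within distance 1 of several accepted
    OTUs goes to the most abundant one (ties: lexicographically smallest
    sequence pair).  Acceptance and exact-match counts are never changed.
    Returns the updated table and the multiset of unassigned pairs.
    """
    # One substitution total across the pair means at least one mate is an
    # exact match, so candidates can be indexed by mate instead of scanned.
    by_fwd: dict[str, list[OTURecord]] = {}
    by_rev: dict[str, list[OTURecord]] = {}
    for r in table.records:
        by_fwd.setdefault(r.fwd, []).append(r)
        by_rev.setdefault(r.rev, []).append(r)

    unassigned: Counter[PairKey] = Counter()
    for (fwd, rev), n in discarded.items():
        candidates = {
            id(r): r
            for r in by_fwd.get(fwd, []) + by_rev.get(rev, [])
            if _hamming_le(r.fwd + r.rev, fwd + rev, 1) is not None
        }
        if candidates:
            best = min(candidates.values(), key=lambda r: (-r.count, r.key))
            best.rescued += n
        else:
            unassigned[(fwd, rev)] += n
    return table, unassigned


def flag_chimeras(
    table: SampleOTUTable,
    fold: float = 2.0,
    require_distinct_parents: bool = False,
) -> SampleOTUTable:
    """Flag OTUs whose two halves are each borrowed from a >= ``fold``-times
    more abundant accepted OTU.

    C is flagged iff accepted records A != C and B != C exist with
    ``A.fwd == C.fwd``, ``B.rev == C.rev``, ``A.count >= fold*C.count`` and
    ``B.count >= fold*C.count``.  Abundance is the exact-match count
    (pre-rescue), keeping flags independent of rescue order.  With
    ``require_distinct_parents`` A and B must also differ from each other.
    Flagged records stay in the table; downstream profiles skip them.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    for c in table.records:
        parents_a = [
            a
            for a in table.records
            if a is not c and a.fwd == c.fwd and a.count >= fold * c.count
        ]
        parents_b = [
            b
            for b in table.records
            if b is not c and b.rev == c.rev and b.count >= fold * c.count
        ]
        if require_distinct_parents:
            c.chimera = any(
                a is not b for a in parents_a for b in parents_b
            )
        else:
            c.chimera = bool(parents_a) and bool(parents_b)
    return table
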