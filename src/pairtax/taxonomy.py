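"""Taxonomic assignment of paired OTUs against a primer-trimmed reference.

Full-length 16S reference sequences are cut to the amplified region with
the PCR primers as a guide, so that an OTU's two 70-nt sub-reads can be
compared end-to-end against the matching reference fragments (orders of
magnitude faster than searching full-length genes, and free of clustering
artifacts since the reference is used unclustered).  Each OTU is searched
exhaustively; hits are collected at six nested identity thresholds
(100, 98, 97, 95, 92, 90%) and a consensus genus or family label is
accepted at the deepest rank that is both specific (modal-label fraction
at the top populated level) and concordant across the populated levels.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import pandas as pd
from Bio import SeqIO

from .iupac import IUPACSequence, count_mismatches, reverse_complement
from .otu import OTURecord, SampleOTUTable

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
DEFAULT_LEVELS = (1.00, 0.98, 0.97, 0.95, 0.92, 0.90)

Lineage = tuple[str, str, str, str, str, str]


def _clean_lineage(ranks: Sequence[str]) -> Lineage:
    out = [r.strip() for r in ranks][:6]
    out += [""] * (6 - len(out))
    return tuple(out)  # type: ignore[return-value]


@dataclass(frozen=True)
class ReferenceEntry:
    accession: str
    seq: str  # full-length gene, ACGTN, U already mapped to T
    lineage: Lineage


@dataclass(frozen=True)
class TrimmedReference:
    """Reference cut to the amplified region, in amplicon orientation."""

    accession: str
    fwd_frag: str  # first read_len bases after the forward primer
    rev_frag: str  # last read_len bases before the reverse primer site
    lineage: Lineage


Hit = tuple[str, float, Lineage]  # (accession, combined identity, lineage)


@dataclass
class HitProfile:
    """Hits per identity threshold; lists are nested by construction."""

    levels: tuple[float, ...]
    hits: dict[float, list[Hit]]

    def top_level(self) -> float | None:
        """Highest threshold with at least one hit, or None."""
        for t in self.levels:
            if self.hits[t]:
                return t
        return None


@dataclass
class Assignment:
    otu_id: str
    lineage: Lineage
    assigned_rank: str  # a rank name, or "unassigned"
    specificity: float  # percent, 0-100
    supporting_hits: int


# ---------------------------------------------------------------------------
# Reference loading and trimming


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def load_references(
    fasta_path: str | Path, lineage_path: str | Path | None = None
) -> list[ReferenceEntry]:
    """Load a reference FASTA plus lineages.

    Lineages come from a two-column TSV ``accession<TAB>d;p;c;o;f;g``
    (SILVA taxonomy export dialect) or, if no TSV is given, from the FASTA
    header after the first space.  Sequences are uppercased, U mapped to T
    and alignment gap characters removed.
    """
    fasta_path = Path(fasta_path)
    lineages: dict[str, Lineage] = {}
    if lineage_path is not None:
        df = pd.read_csv(
            lineage_path, sep="\t", header=None, names=["accession", "lineage"],
            dtype=str, comment="#",
        )
        for row in df.itertuples(index=False):
            lineages[str(row.accession)] = _clean_lineage(str(row.lineage).split(";"))
    entries = []
    with _open_maybe_gzip(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper().replace("U", "T").replace("-", "").replace(".", "")
            if rec.id in lineages:
                lineage = lineages[rec.id]
            else:
                desc = rec.description.split(None, 1)
                lineage = _clean_lineage(desc[1].split(";")) if len(desc) > 1 else _clean_lineage([])
            entries.append(ReferenceEntry(accession=rec.id, seq=seq, lineage=lineage))
    return entries


def _best_site(seq: str, pattern: str, max_mismatch: int, take_last: bool) -> int | None:
    """Start of the best IUPAC match of ``pattern`` in ``seq``.

    Fewest mismatches wins; among equals the 5'-most site is taken unless
    ``take_last`` (used for the reverse-primer site, which bounds the
    amplicon's 3' end)."""
    plen = len(pattern)
    best_start, best_mm = None, None
    for start in range(len(seq) - plen + 1):
        mm = count_mismatches(pattern, seq[start : start + plen])
        if mm > max_mismatch:
            continue
        if best_mm is None or mm < best_mm or (mm == best_mm and take_last):
            best_start, best_mm = start, mm
    return best_start


def trim_reference(
    entry: ReferenceEntry,
    fwd_primer: IUPACSequence | str,
    rev_primer: IUPACSequence | str,
    read_len: int = 70,
    max_primer_mismatch: int = 1,
) -> TrimmedReference | None:
    """Cut one full-length reference to the amplified region.

    Both primers are given in amplicon orientation (the reverse primer is
    reverse-complemented internally to locate its binding site on the
    given strand).  Returns ``None`` when either primer has no site within
    ``max_primer_mismatch`` mismatches or the inter-primer region is
    shorter than ``read_len``.
    """
    rev_site_pattern = reverse_complement(str(rev_primer))
    f_start = _best_site(entry.seq, str(fwd_primer), max_primer_mismatch, take_last=False)
    r_start = _best_site(entry.seq, rev_site_pattern, max_primer_mismatch, take_last=True)
    if f_start is None or r_start is None:
        return None
    region_start = f_start + len(str(fwd_primer))
    region_end = r_start
    if region_end - region_start < read_len:
        return None
    region = entry.seq[region_start:region_end]
    return TrimmedReference(
        accession=entry.accession,
        fwd_frag=region[:read_len],
        rev_frag=region[-read_len:],
        lineage=entry.lineage,
    )


def trim_database(
    entries: Iterable[ReferenceEntry],
    fwd_primer: IUPACSequence | str,
    rev_primer: IUPACSequence | str,
    read_len: int = 70,
    max_primer_mismatch: int = 1,
) -> tuple[list[TrimmedReference], int]:
    """Trim every entry; returns (database, n_rejected)."""
    db, rejected = [], 0
    for e in entries:
        t = trim_reference(e, fwd_primer, rev_primer, read_len, max_primer_mismatch)
        if t is None:
            rejected += 1
        else:
            db.append(t)
    return db, rejected


# ---------------------------------------------------------------------------
# Identity and search


def identity(query: str, ref: str) -> float:
    """Global-alignment identity of two sequences in [0, 1].

    Defined as 1 − d/L with d the Levenshtein distance (unit costs for
    substitutions and gaps, end-to-end) and L the longer length — the
    match fraction of a gap-minimal optimal alignment.  Symmetric and
    independent of alignment-path tie-breaking.
    """
    if not query or not ref:
        raise ValueError("identity of empty sequence is undefined")
    d = edlib.align(query, ref, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(query), len(ref))


def combined_identity(otu: OTURecord, ref: TrimmedReference) -> float:
    """Mean of the forward- and reverse-fragment identities.

    The OTU's reverse read is in read orientation; the reference fragment
    is amplicon-oriented and is reverse-complemented before comparison.
    """
    return (
        identity(otu.fwd, ref.fwd_frag)
        + identity(otu.rev, reverse_complement(ref.rev_frag))
    ) / 2.0


def search_hits(
    otu: OTURecord,
    db: Sequence[TrimmedReference],
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> HitProfile:
    """Exhaustive search of one OTU against the trimmed database.

    At each threshold level the profile lists every reference whose
    combined identity reaches the level, so hit lists are nested from the
    strictest level downward.
    """
    if not db:
        raise ValueError("empty reference database")
    levels = tuple(sorted(levels, reverse=True))
    scored: list[Hit] = []
    floor = levels[-1]
    for ref in db:
        ident = combined_identity(otu, ref)
        if ident >= floor:
            scored.append((ref.accession, ident, ref.lineage))
    hits = {t: [h for h in scored if h[1] >= t] for t in levels}
    return HitProfile(levels=levels, hits=hits)


# ---------------------------------------------------------------------------
# Consensus labelling


def specificity(
    hits: Sequence[Hit], rank: str
) -> tuple[str, float, int]:
    """Modal label at ``rank`` among hits, its percent share, and the
    number of hits carrying a non-empty label at that rank.

    Ties on the mode go to the lexicographically first label.  Hits with
    an empty label at the rank are excluded from both numerator and
    denominator.  Returns ("", 0.0, 0) when no hit is labelled.
    """
    idx = RANKS.index(rank)
    labels = [h[2][idx] for h in hits if h[2][idx]]
    if not labels:
        return "", 0.0, 0
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    modal = min(counts, key=lambda k: (-counts[k], k))
    return modal, 100.0 * counts[modal] / len(labels), len(labels)


def _shared_prefix(lineages: Sequence[Lineage]) -> Lineage:
    """Deepest lineage prefix common to all (empty slots beyond it)."""
    out = [""] * 6
    for i in range(6):
        vals = {lin[i] for lin in lineages}
        if len(vals) == 1 and "" not in vals:
            out[i] = vals.pop()
        else:
            break
    return tuple(out)  # type: ignore[return-value]


def _lineage_upto(lineage: Lineage, rank: str) -> Lineage:
    idx = RANKS.index(rank)
    return tuple(list(lineage[: idx + 1]) + [""] * (5 - idx))  # type: ignore[return-value]


def consensus_label(
    profile: HitProfile, otu_id: str = "", min_spec: float = 50.0
) -> Assignment:
    """Resolve a consensus taxonomic label from a multi-threshold profile.

    Let T be the highest threshold with any hit.  The genus modal label at
    T is accepted iff its specificity is at least ``min_spec`` percent and
    every lower populated level has the same modal genus (concordance);
    failing genus, the same test is applied at family; failing both, the
    deepest lineage prefix shared by all hits at T is emitted.  The
    reported lineage is the modal hit's lineage truncated at the accepted
    rank.
    """
    top = profile.top_level()
    if top is None:
        return Assignment(otu_id, _clean_lineage([]), "unassigned", 0.0, 0)
    top_hits = profile.hits[top]
    populated = [t for t in profile.levels if profile.hits[t]]

    for rank in ("genus", "family"):
        modal, pct, n = specificity(top_hits, rank)
        if not modal or pct < min_spec:
            continue
        if any(specificity(profile.hits[t], rank)[0] != modal for t in populated):
            continue
        donor = next(h[2] for h in top_hits if h[2][RANKS.index(rank)] == modal)
        return Assignment(otu_id, _lineage_upto(donor, rank), rank, pct, n)

    shared = _shared_prefix([h[2] for h in top_hits])
    depth = sum(1 for r in shared if r)
    rank_name = RANKS[depth - 1] if depth else "unassigned"
    return Assignment(otu_id, shared, rank_name, 0.0 if not depth else 100.0, len(top_hits))


def classify_table(
    table: SampleOTUTable,
    db: Sequence[TrimmedReference],
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    min_spec: float = 50.0,
) -> list[Assignment]:
    """Assign every non-chimeric OTU in a sample table."""
    out = []
    for rec in table.non_chimeric():
        profile = search_hits(rec, db, levels)
        out.append(consensus_label(profile, otu_id=rec.otu_id, min_spec=min_spec))
    return out


def assignments_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "otu_id": a.otu_id,
                "lineage": ";".join(a.lineage).rstrip(";"),
                "assigned_rank": a.assigned_rank,
                "specificity": a.specificity,
                "supporting_hits": a.supporting_hits,
            }
            for a in assignments
        ],
        columns=["otu_id", "lineage", "assigned_rank", "specificity", "supporting_hits"],
    )
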