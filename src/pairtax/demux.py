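"""Dual-barcode demultiplexing of paired-end amplicon reads.

Each sample is identified by the combination of a forward and a reverse
8-nt barcode, one on each mate.  A read pair is accepted for a sample
only when, on both mates, the barcode matches exactly and the primer
matches with zero mismatches under IUPAC expansion; the two linker bases
between barcode and primer are skipped.  Dual barcoding makes hybrid
molecules formed after pooling of per-sample PCR products detectable:
a pair whose two barcodes are both valid but belong to different
samples is rejected as a cross-sample chimera.

Base-call quality strings are carried through but never consulted:
filtering is by abundance downstream, not by Phred score.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .iupac import IUPACSequence, matches

REJECT_MISMATCH = "barcode/primer mismatch"
REJECT_CROSS = "cross-sample chimera"


@dataclass(frozen=True)
class SampleMapEntry:
    sample_id: str
    fwd_barcode: str
    rev_barcode: str
    fwd_primer: IUPACSequence
    rev_primer: IUPACSequence
    linker_len: int = 2
    library_id: str = ""


@dataclass
class SampleMap:
    """Validated sample ↔ (barcode pair, primer pair) bindings."""

    entries: list[SampleMapEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("sample map has no entries")
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids) or any(not i for i in ids):
            raise ValueError("sample ids must be unique and non-empty")
        lengths = {len(e.fwd_barcode) for e in self.entries} | {
            len(e.rev_barcode) for e in self.entries
        }
        if len(lengths) != 1:
            raise ValueError(f"barcodes must share one length, got {sorted(lengths)}")
        pairs = [(e.fwd_barcode, e.rev_barcode) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (fwd, rev) barcode pair across samples")

    @property
    def barcode_len(self) -> int:
        return len(self.entries[0].fwd_barcode)

    def __iter__(self) -> Iterator[SampleMapEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: str
    rev_qual: str

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(
            self.rev_qual
        ):
            raise ValueError(f"sequence/quality length mismatch in {self.read_id}")


@dataclass(frozen=True)
class TrimmedPair:
    """Fixed-length 5' and 3' sub-reads after technical-sequence removal."""

    read_id: str
    fwd: str
    rev: str


class MappingError(ValueError):
    pass


_COLUMN_ALIASES = {
    "sampleid": "sample_id",
    "#sampleid": "sample_id",
    "fwdbarcode": "fwd_barcode",
    "revbarcode": "rev_barcode",
    "fwdprimer": "fwd_primer",
    "revprimer": "rev_primer",
    "linkerlen": "linker_len",
    "libraryid": "library_id",
}


def parse_mapping(path: str | Path) -> SampleMap:
    """Read a tab-delimited mapping file into a validated :class:`SampleMap`.

    The header must name SampleID, FwdBarcode, RevBarcode, FwdPrimer and
    RevPrimer (case-insensitive); LinkerLen (default 2) and LibraryID are
    optional.  Lines starting with ``#`` after the header are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None, skip_blank_lines=True)
    df.columns = [_COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    df = df[~df["sample_id"].str.startswith("#")]
    required = {"sample_id", "fwd_barcode", "rev_barcode", "fwd_primer", "rev_primer"}
    missing = required - set(df.columns)
    if missing:
        raise MappingError(f"{path}: missing column(s) {sorted(missing)}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            entries.append(
                SampleMapEntry(
                    sample_id=str(row.sample_id),
                    fwd_barcode=str(row.fwd_barcode).upper(),
                    rev_barcode=str(row.rev_barcode).upper(),
                    fwd_primer=IUPACSequence(str(row.fwd_primer)),
                    rev_primer=IUPACSequence(str(row.rev_primer)),
                    linker_len=int(getattr(row, "linker_len", 2) or 2),
                    library_id=str(getattr(row, "library_id", "") or ""),
                )
            )
        except (ValueError, TypeError) as exc:
            raise MappingError(f"{path}: malformed row at line {i}: {exc}") from exc
    try:
        return SampleMap(entries)
    except ValueError as exc:
        raise MappingError(f"{path}: {exc}") from exc


def match_prefix(
    read: str, barcode: str, linker_len: int, primer: str
) -> bool:
    """True iff the read starts with the exact barcode followed, after
    ``linker_len`` skipped bases, by a zero-mismatch IUPAC match of the
    primer.  Too-short reads simply fail."""
    tech_len = len(barcode) + linker_len + len(primer)
    if len(read) < tech_len:
        return False
    if read[: len(barcode)] != barcode:
        return False
    start = len(barcode) + linker_len
    return matches(primer, read[start : start + len(primer)])


@dataclass
class DemuxResult:
    assigned: dict[str, list[ReadPair]]
    rejected: list[tuple[ReadPair, str]]

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def report(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "category": "accepted", "reads": len(v)}
            for s, v in self.assigned.items()
        ]
        for reason in (REJECT_MISMATCH, REJECT_CROSS):
            rows.append(
                {
                    "sample_id": "*",
                    "category": reason,
                    "reads": sum(r == reason for _, r in self.rejected),
                }
            )
        return pd.DataFrame(rows)


def demultiplex(pairs: Iterable[ReadPair], sample_map: SampleMap) -> DemuxResult:
    """Assign each read pair to exactly one sample bucket or reject it.

    Acceptance requires a perfect barcode+primer match on both mates for
    a single sample.  Pairs whose forward barcode and reverse barcode each
    occur in the map but whose combination names no sample are rejected as
    cross-sample chimeras; all other failures as barcode/primer mismatch.
    """
    by_pair = {(e.fwd_barcode, e.rev_barcode): e for e in sample_map}
    fwd_codes = {e.fwd_barcode for e in sample_map}
    rev_codes = {e.rev_barcode for e in sample_map}
    blen = sample_map.barcode_len

    assigned: dict[str, list[ReadPair]] = {e.sample_id: [] for e in sample_map}
    rejected: list[tuple[ReadPair, str]] = []
    for pair in pairs:
        fbc, rbc = pair.fwd_seq[:blen], pair.rev_seq[:blen]
        entry = by_pair.get((fbc, rbc))
        if entry is not None and match_prefix(
            pair.fwd_seq, entry.fwd_barcode, entry.linker_len, entry.fwd_primer
        ) and match_prefix(
            pair.rev_seq, entry.rev_barcode, entry.linker_len, entry.rev_primer
        ):
            assigned[entry.sample_id].append(pair)
        elif entry is None and fbc in fwd_codes and rbc in rev_codes:
            rejected.append((pair, REJECT_CROSS))
        else:
            rejected.append((pair, REJECT_MISMATCH))
    return DemuxResult(assigned=assigned, rejected=rejected)


def strip_and_trim(
    pair: ReadPair, entry: SampleMapEntry, read_len: int = 70
) -> TrimmedPair | None:
    """Strip barcode+linker+primer from each mate's 5' end and keep exactly
    ``read_len`` payload bases; ``None`` when a mate is too short."""
    f_off = len(entry.fwd_barcode) + entry.linker_len + len(entry.fwd_primer)
    r_off = len(entry.rev_barcode) + entry.linker_len + len(entry.rev_primer)
    fwd = pair.fwd_seq[f_off : f_off + read_len]
    rev = pair.rev_seq[r_off : r_off + read_len]
    if len(fwd) < read_len or len(rev) < read_len:
        return None
    return TrimmedPair(read_id=pair.read_id, fwd=fwd, rev=rev)


def trim_sample(
    pairs: Iterable[ReadPair], entry: SampleMapEntry, read_len: int = 70
) -> tuple[list[TrimmedPair], int]:
    """Trim all accepted pairs of one sample; returns (trimmed, n_too_short)."""
    trimmed, short = [], 0
    for pair in pairs:
        t = strip_and_trim(pair, entry, read_len)
        if t is None:
            short += 1
        else:
            trimmed.append(t)
    return trimmed, short


# ---------------------------------------------------------------------------
# FASTQ plumbing


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_pairs(fwd_fastq: str | Path, rev_fastq: str | Path) -> Iterator[ReadPair]:
    """Stream synchronized paired FASTQ files as :class:`ReadPair` records.

    Raises on desynchronized inputs (differing ids before the first space,
    or differing record counts).
    """
    with _open_text(fwd_fastq) as fh1, _open_text(rev_fastq) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        sentinel = object()
        while True:
            rec1 = next(it1, sentinel)
            rec2 = next(it2, sentinel)
            if rec1 is sentinel and rec2 is sentinel:
                return
            if rec1 is sentinel or rec2 is sentinel:
                raise ValueError("paired FASTQ files have different record counts")
            (id1, seq1, q1), (id2, seq2, q2) = rec1, rec2
            base1, base2 = id1.split()[0], id2.split()[0]
            if base1.removesuffix("/1") != base2.removesuffix("/2"):
                raise ValueError(f"desynchronized FASTQ records: {id1!r} vs {id2!r}")
            yield ReadPair(base1, seq1.upper(), seq2.upper(), q1, q2)


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def demultiplex_files(
    fwd_fastq: str | Path,
    rev_fastq: str | Path,
    sample_map: SampleMap,
    out_dir: str | Path,
) -> pd.DataFrame:
    """File-level demultiplexing: writes ``<sample>_R1.fastq``/``_R2.fastq``
    per sample plus ``demux_report.tsv``; returns the report frame."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = demultiplex(read_pairs(fwd_fastq, rev_fastq), sample_map)
    for sample_id, reads in result.assigned.items():
        write_fastq(
            ((r.read_id, r.fwd_seq, r.fwd_qual) for r in reads),
            out_dir / f"{sample_id}_R1.fastq",
        )
        write_fastq(
            ((r.read_id, r.rev_seq, r.rev_qual) for r in reads),
            out_dir / f"{sample_id}_R2.fastq",
        )
    report = result.report()
    report.to_csv(out_dir / "demux_report.tsv", sep="\t", index=False)
    return report
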