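"""Synthetic mock communities with full ground-truth bookkeeping.

Real pipeline validation uses mock communities — mixtures of known 16S
phylotypes at known proportions — because they expose quantification
bias, spurious OTUs and chimera formation against a known truth.  This
module generates the same kind of control data entirely in silico:
full-length-like reference templates whose genus structure is enforced
by construction (within-genus insert identity >= 97%, between-genus
< 90%), and barcoded paired reads drawn from a community design with
i.i.d. substitution errors, optional template-recombination chimeras and
optional corruption of technical bases.  Every emitted read carries a
truth record, so demultiplexing, OTU picking, rescue, chimera flagging
and classification can each be scored exactly.

The error model is substitution-only (Illumina-like); qualities are
emitted as a constant since no stage consults them.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .demux import SampleMap, SampleMapEntry, write_fastq
from .iupac import (
    IUPAC,
    IUPACSequence,
    PRIMER_515F,
    PRIMER_806R,
    expand,
    reverse_complement,
)
from .profiles import Profile
from .taxonomy import Lineage, ReferenceEntry, TrimmedReference, identity, trim_reference

_BASES = "ACGT"


@dataclass(frozen=True)
class MockDesign:
    """A mock community: members with relative abundances plus read-level
    noise settings."""

    name: str
    members: tuple[tuple[str, float], ...]  # (template accession, fraction)
    n_reads: int
    error_rate: float = 0.0
    chimera_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"member fractions sum to {total}, not 1")
        if not (0 <= self.error_rate < 1 and 0 <= self.chimera_rate < 1):
            raise ValueError("rates must lie in [0, 1)")


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    template: str
    template_3p: str | None = None  # second parent of a chimeric pair
    breakpoint: int | None = None  # position in the 2*read_len concatenation
    error_positions: tuple[int, ...] = ()
    technical_error: bool = False

    @property
    def is_chimera(self) -> bool:
        return self.template_3p is not None


@dataclass
class GroundTruth:
    """Everything needed to score a pipeline run against the simulation."""

    design: MockDesign
    reads: list[ReadTruth]
    templates: dict[str, TrimmedReference]  # accession -> truth fragments

    def expected_pairs(self) -> dict[str, tuple[str, str]]:
        """Per template, the error-free trimmed (fwd, rev) read pair in
        read orientation — what dereplication should recover."""
        return {
            acc: (t.fwd_frag, reverse_complement(t.rev_frag))
            for acc, t in self.templates.items()
        }


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _mutate(rng: random.Random, seq: str, n_sites: int) -> str:
    sites = rng.sample(range(len(seq)), n_sites)
    out = list(seq)
    for i in sites:
        out[i] = rng.choice([b for b in _BASES if b != out[i]])
    return "".join(out)


def synth_references(
    n: int,
    n_genera: int,
    seed: int = 42,
    fwd_primer: str = PRIMER_515F,
    rev_primer: str = PRIMER_806R,
    insert_len: int = 253,
    pad_len: int = 120,
) -> list[ReferenceEntry]:
    """Generate ``n`` full-length-like reference templates in ``n_genera``
    genera.

    Each template is random padding + a concrete expansion of the forward
    primer + an insert of ``insert_len`` + the reverse complement of an
    expansion of the reverse primer + padding.  Genus structure is imposed
    on the inserts: members of one genus differ from the genus seed insert
    at at most 3 sites (pairwise identity >= 97% for the default V4-like
    253-nt insert), and genus seed inserts are independent random
    sequences re-drawn until all between-genus identities fall below 90%.
    Accessions are ``PT01``, ``PT02``, ...; lineages share a domain and
    phylum and split into per-genus families and genera.
    """
    if not 1 <= n_genera <= n:
        raise ValueError("need n >= n_genera >= 1")
    if insert_len < 100:
        raise ValueError("insert too short to guarantee the genus identity gaps")
    rng = random.Random(seed)

    seeds: list[str] = []
    for _ in range(n_genera):
        for _attempt in range(100):
            cand = _random_seq(rng, insert_len)
            if all(identity(cand, s) < 0.90 for s in seeds):
                seeds.append(cand)
                break
        else:
            raise ValueError("could not satisfy the between-genus identity bound")

    # Round-robin members over genera; each non-seed member mutates 1-3 sites.
    entries: list[ReferenceEntry] = []
    members_of: dict[int, int] = {g: 0 for g in range(n_genera)}
    for i in range(n):
        g = i % n_genera
        insert = seeds[g] if members_of[g] == 0 else _mutate(rng, seeds[g], rng.randint(1, 3))
        members_of[g] += 1
        seq = (
            _random_seq(rng, pad_len)
            + expand(fwd_primer, rng)
            + insert
            + reverse_complement(expand(rev_primer, rng))
            + _random_seq(rng, pad_len)
        )
        lineage: Lineage = (
            "Bacteria",
            "SimPhylum",
            "SimClass",
            "SimOrder",
            f"Family{g + 1:02d}",
            f"Genus{g + 1:02d}",
        )
        entries.append(ReferenceEntry(accession=f"PT{i + 1:02d}", seq=seq, lineage=lineage))
    return entries


def preset_designs(seed: int = 42) -> dict[str, MockDesign]:
    """The four study-style community designs.

    * ``mc1`` — 17 phylotypes, equimolar, 10,000 read pairs.
    * ``mc2`` — 55 phylotypes, equimolar, 50,000 read pairs.
    * ``mc3`` — 55 phylotypes, staggered log-spaced over three decades.
    * ``mc4`` — 50 phylotypes between 0.001% and 2.49%, including members
      at exactly 0.1%, 0.01% and 0.001% relative abundance.

    All presets default to zero error and chimera rates; callers override
    noise settings with :func:`dataclasses.replace`.
    """
    mc1 = MockDesign(
        "mc1",
        tuple((f"PT{i + 1:02d}", 1 / 17) for i in range(17)),
        n_reads=10_000,
        seed=seed,
    )
    mc2 = MockDesign(
        "mc2",
        tuple((f"PT{i + 1:02d}", 1 / 55) for i in range(55)),
        n_reads=50_000,
        seed=seed,
    )
    raw = [10 ** (-3 * i / 54) for i in range(55)]
    total = sum(raw)
    mc3 = MockDesign(
        "mc3",
        tuple((f"PT{i + 1:02d}", raw[i] / total) for i in range(55)),
        n_reads=50_000,
        seed=seed,
    )
    # Three very low members at 0.1%, 0.01% and 0.001%; the remaining 47
    # linearly spaced with a 2.49% maximum so the whole sums to one.
    lows = [1e-3, 1e-4, 1e-5]
    rest_total = 1.0 - sum(lows)
    hi = 0.0249
    lo = 2 * rest_total / 47 - hi
    rest = [lo + (hi - lo) * i / 46 for i in range(47)]
    fracs = rest + lows
    mc4 = MockDesign(
        "mc4",
        tuple((f"PT{i + 1:02d}", fracs[i]) for i in range(50)),
        n_reads=20_000,
        seed=seed,
    )
    return {"mc1": mc1, "mc2": mc2, "mc3": mc3, "mc4": mc4}


def make_sample_map(
    n_samples: int = 1,
    seed: int = 42,
    fwd_primer: str = PRIMER_515F,
    rev_primer: str = PRIMER_806R,
    barcode_len: int = 8,
    linker_len: int = 2,
) -> SampleMap:
    """Random distinct dual-barcode sample map for simulations."""
    rng = random.Random(seed)
    used: set[tuple[str, str]] = set()
    entries = []
    for i in range(n_samples):
        while True:
            pair = (_random_seq(rng, barcode_len), _random_seq(rng, barcode_len))
            if pair not in used:
                used.add(pair)
                break
        entries.append(
            SampleMapEntry(
                sample_id=f"S{i + 1:02d}",
                fwd_barcode=pair[0],
                rev_barcode=pair[1],
                fwd_primer=IUPACSequence(fwd_primer),
                rev_primer=IUPACSequence(rev_primer),
                linker_len=linker_len,
                library_id="simlib",
            )
        )
    return SampleMap(entries)


def _corrupt_technical(
    rng: random.Random, tech: str, primer: str, barcode_len: int, linker_len: int
) -> str:
    """Substitute one technical base so the pair can no longer match:
    barcode positions get any other base; primer positions get a base
    outside the IUPAC expansion (N positions are avoided)."""
    plen = len(primer)
    while True:
        pos = rng.randrange(len(tech))
        if pos < barcode_len:
            choices = [b for b in _BASES if b != tech[pos]]
        elif pos < barcode_len + linker_len:
            continue  # linker is never checked; corrupting it proves nothing
        else:
            code = primer[pos - barcode_len - linker_len]
            choices = [b for b in _BASES if b not in IUPAC[code]]
            if not choices:  # N accepts everything
                continue
        return tech[:pos] + rng.choice(choices) + tech[pos + 1 :]


def _apply_errors(
    rng: random.Random, seq: str, rate: float, offset: int
) -> tuple[str, list[int]]:
    if rate == 0:
        return seq, []
    out = list(seq)
    positions = []
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in _BASES if b != out[i]])
            positions.append(offset + i)
    return "".join(out), positions


def simulate_reads(
    design: MockDesign,
    refs: Sequence[ReferenceEntry],
    map_entry: SampleMapEntry,
    read_len: int = 70,
    technical_error_rate: float = 0.0,
    chimera_breakpoint: str = "boundary",
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], GroundTruth]:
    """Draw ``design.n_reads`` barcoded read pairs for one sample.

    Template payloads are obtained by primer-trimming each referenced
    template exactly as the classifier trims its database, so the
    simulator's truth fragments and the pipeline's coordinates agree by
    construction.  With probability ``chimera_rate`` a pair recombines two
    distinct templates — at the mate boundary by default (the detectable
    case), or at a uniform position in the 2×``read_len`` concatenation
    with ``chimera_breakpoint="uniform"``.  Substitution errors at
    ``error_rate`` hit payload bases only; with probability
    ``technical_error_rate`` one barcode or primer base is corrupted
    instead (recorded, and guaranteed to defeat demultiplexing).  Returns
    (fwd records, rev records, truth) with records as (id, seq, qual)
    triples; a fixed design seed gives byte-identical output.
    """
    rng = random.Random(design.seed)
    by_acc = {r.accession: r for r in refs}
    templates: dict[str, TrimmedReference] = {}
    for acc, _frac in design.members:
        if acc not in by_acc:
            raise ValueError(f"design member {acc} has no reference")
        trimmed = trim_reference(
            by_acc[acc], map_entry.fwd_primer, map_entry.rev_primer, read_len
        )
        if trimmed is None:
            raise ValueError(f"reference {acc} does not span the amplicon")
        templates[acc] = trimmed

    accs = [acc for acc, _ in design.members]
    weights = [f for _, f in design.members]
    pairs = {acc: (t.fwd_frag, reverse_complement(t.rev_frag)) for acc, t in templates.items()}

    linker = "CA"[: map_entry.linker_len].ljust(map_entry.linker_len, "T")
    blen = len(map_entry.fwd_barcode)

    fwd_out, rev_out, truths = [], [], []
    for i in range(design.n_reads):
        rid = f"{design.name}_{i:06d}"
        acc = rng.choices(accs, weights=weights)[0]
        fwd_payload, rev_payload = pairs[acc]
        acc2: str | None = None
        breakpoint: int | None = None
        if design.chimera_rate and rng.random() < design.chimera_rate and len(accs) > 1:
            acc2 = rng.choice([a for a in accs if a != acc])
            f2, r2 = pairs[acc2]
            if chimera_breakpoint == "boundary":
                breakpoint = read_len
            else:
                breakpoint = rng.randrange(1, 2 * read_len)
            cat = (fwd_payload + rev_payload)[:breakpoint] + (f2 + r2)[breakpoint:]
            fwd_payload, rev_payload = cat[:read_len], cat[read_len:]

        fwd_payload, errs_f = _apply_errors(rng, fwd_payload, design.error_rate, 0)
        rev_payload, errs_r = _apply_errors(rng, rev_payload, design.error_rate, read_len)

        fwd_tech = map_entry.fwd_barcode + linker + expand(map_entry.fwd_primer, rng)
        rev_tech = map_entry.rev_barcode + linker + expand(map_entry.rev_primer, rng)
        tech_err = bool(technical_error_rate) and rng.random() < technical_error_rate
        if tech_err:
            if rng.random() < 0.5:
                fwd_tech = _corrupt_technical(
                    rng, fwd_tech, map_entry.fwd_primer, blen, map_entry.linker_len
                )
            else:
                rev_tech = _corrupt_technical(
                    rng, rev_tech, map_entry.rev_primer, blen, map_entry.linker_len
                )

        fwd_seq = fwd_tech + fwd_payload
        rev_seq = rev_tech + rev_payload
        fwd_out.append((rid, fwd_seq, "I" * len(fwd_seq)))
        rev_out.append((rid, rev_seq, "I" * len(rev_seq)))
        truths.append(
            ReadTruth(
                read_id=rid,
                template=acc,
                template_3p=acc2,
                breakpoint=breakpoint,
                error_positions=tuple(errs_f + errs_r),
                technical_error=tech_err,
            )
        )
    return fwd_out, rev_out, GroundTruth(design=design, reads=truths, templates=templates)


def expected_profile(
    design: MockDesign, refs: Sequence[ReferenceEntry], rank: str = "genus"
) -> Profile:
    """The in-silico expected composition of a design at ``rank``."""
    from .taxonomy import RANKS

    idx = RANKS.index(rank)
    by_acc = {r.accession: r for r in refs}
    masses: dict[str, float] = {}
    for acc, frac in design.members:
        label = by_acc[acc].lineage[idx]
        masses[label] = masses.get(label, 0.0) + frac
    total = sum(masses.values())
    return Profile(
        sample_id=f"{design.name}_expected",
        rank=rank,
        abundances={k: v / total for k, v in masses.items()},
    )


def write_simulation(
    out_dir: str | Path,
    refs: Sequence[ReferenceEntry],
    fwd_records: Sequence[tuple[str, str, str]],
    rev_records: Sequence[tuple[str, str, str]],
    truth: GroundTruth,
    sample_map: SampleMap,
) -> None:
    """Write FASTQ pair, mapping file, reference FASTA + lineage TSV and
    the per-read truth table under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fastq(fwd_records, out_dir / "reads_R1.fastq")
    write_fastq(rev_records, out_dir / "reads_R2.fastq")
    with open(out_dir / "references.fasta", "w") as fh:
        for r in refs:
            fh.write(f">{r.accession}\n{r.seq}\n")
    with open(out_dir / "lineages.tsv", "w") as fh:
        for r in refs:
            fh.write(f"{r.accession}\t{';'.join(r.lineage)}\n")
    pd.DataFrame(
        [
            {
                "SampleID": e.sample_id,
                "FwdBarcode": e.fwd_barcode,
                "RevBarcode": e.rev_barcode,
                "FwdPrimer": str(e.fwd_primer),
                "RevPrimer": str(e.rev_primer),
                "LinkerLen": e.linker_len,
                "LibraryID": e.library_id,
            }
            for e in sample_map
        ]
    ).to_csv(out_dir / "mapping.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "read_id": t.read_id,
                "template": t.template,
                "template_3p": t.template_3p or "",
                "breakpoint": "" if t.breakpoint is None else t.breakpoint,
                "n_errors": len(t.error_positions),
                "technical_error": t.technical_error,
            }
            for t in truth.reads
        ]
    ).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
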