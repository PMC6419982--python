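import random

import pytest

import pairtax as pt


def pairs_from_records(fwd_records, rev_records):
    """Zip simulator FASTQ triples into ReadPair objects."""
    return [
        pt.ReadPair(f[0], f[1], r[1], f[2], r[2])
        for f, r in zip(fwd_records, rev_records)
    ]


def levenshtein(a: str, b: str) -> int:
    """Full-DP edit distance oracle (unit costs, end-to-end)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[len(b)]


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def refs17():
    return pt.synth_references(17, 17, seed=42)


@pytest.fixture(scope="session")
def refs55():
    return pt.synth_references(55, 55, seed=42)


@pytest.fixture(scope="session")
def sample_map():
    return pt.make_sample_map(2, seed=42)


@pytest.fixture(scope="session")
def mc1_sim(refs17, sample_map):
    design = pt.preset_designs(seed=42)["mc1"]
    fwd, rev, truth = pt.simulate_reads(design, refs17, sample_map.entries[0])
    return fwd, rev, truth


@pytest.fixture(scope="session")
def mc1_table(mc1_sim, sample_map):
    fwd, rev, truth = mc1_sim
    result = pt.demultiplex(pairs_from_records(fwd, rev), sample_map)
    trimmed, _ = pt.trim_sample(result.assigned["S01"], sample_map.entries[0])
    table, discarded = pt.pick_otus(
        pt.dereplicate(trimmed), len(trimmed), 0.001, "S01"
    )
    return table, discarded
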