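import random

import pytest

from operon_recruit.model import build_annotation


@pytest.fixture
def rng():
    return random.Random(20260920)


def make_genome(genome_id, layout, gap=50, length=900, start=101):
    """Build a one-replicon genome from a compact layout description.

    ``layout`` is a list of (role, strand) or (role, strand, gap_before)
    tuples in gene order; roles are family names or None for anonymous
    genes. Returns (annotation, hit_rows) where hit_rows are dicts ready for
    a family-hit DataFrame.
    """
    rows = []
    hits = []
    pos = start
    for i, item in enumerate(layout):
        role, strand, *rest = item
        gap_before = rest[0] if rest else gap
        if i > 0:
            pos += gap_before
        s, e = pos, pos + length - 1
        pos = e + 1
        tag = f"{genome_id}_g{i:03d}"
        rows.append(("chrom", tag, s, e, strand, f"p{i:03d}"))
        if role is not None:
            hits.append(
                {
                    "protein_id": f"{genome_id}|p{i:03d}",
                    "family": role,
                    "evalue": 1e-30,
                    "score": 200.0,
                }
            )
    return build_annotation(genome_id, rows), hits


@pytest.fixture
def genome_factory():
    return make_genome
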