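import numpy as np
import pytest

from sutura.contacts import (
    BONE_VOCABULARY,
    ContactRecord,
    ContactSegment,
    ContactTable,
    SutureDepth,
)

SPATIAL = ("p", "o", "u", "c", "cb", "t")


def random_contact_table(rng: np.random.Generator, n_taxa: int = 3,
                         n_pairs: int = 6, p_unknown_depth: float = 0.15,
                         p_absent: float = 0.2, p_unknown: float = 0.05,
                         max_segments: int = 2) -> ContactTable:
    """Small random table used by the property checks."""
    bones = sorted(b for b in BONE_VOCABULARY if b not in ("nasal", "columella"))
    all_pairs = [(a, b) for i, a in enumerate(bones) for b in bones[i + 1:]]
    idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    pairs = [all_pairs[i] for i in sorted(idx)]
    table = ContactTable()
    for t in range(n_taxa):
        taxon = f"tax{t + 1}"
        for a, b in pairs:
            r = rng.random()
            if r < p_unknown:
                table.add(taxon, ContactRecord(a, b, "unknown"))
            elif r < p_unknown + p_absent:
                table.add(taxon, ContactRecord(a, b, "absent"))
            else:
                n_seg = int(rng.integers(1, max_segments + 1))
                segs = tuple(
                    ContactSegment(
                        SPATIAL[rng.integers(6)],
                        SutureDepth(None)
                        if rng.random() < p_unknown_depth
                        else SutureDepth(int(rng.integers(4))),
                    )
                    for _ in range(n_seg)
                )
                table.add(taxon, ContactRecord(a, b, "present", segs))
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
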