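import numpy as np
import pandas as pd
import pytest

from tilescreen import synthetic_data as syn
from tilescreen.intervals import GenomicInterval


@pytest.fixture(scope="session")
def fixture_genome():
    return syn.generate_genome_fixture(seed=1)


@pytest.fixture(scope="session")
def toy_manifest(fixture_genome):
    """Small hand-laid manifest: 12 hDel-targeting + 4 non-targeting guides."""
    hd = fixture_genome.hdels.head(12)
    rows = []
    rng = np.random.default_rng(99)
    for i, (_, h) in enumerate(hd.iterrows()):
        mid = (h.start + h.end) // 2
        rows.append((f"sg{i}", None, "hdel", h.chrom, mid - 10, mid + 10, h["name"]))
    for i in range(4):
        rows.append((f"nt{i}", None, "non-targeting", None, None, None, ""))
    man = pd.DataFrame(
        rows, columns=["id", "spacer", "category", "chrom", "start", "end", "hdel_id"]
    )
    man["spacer"] = [
        "G" + "".join(rng.choice(list("ACGT"), 19)) for _ in range(len(man))
    ]
    return man


def tiling_screen(n_hdels=40, guides_per_hdel=10, planted=(), lfc=-1.5,
                  depth=500.0, dispersion=0.05, n_replicates=2, n_individuals=1,
                  seed=0):
    """Synthetic tiled screen: one 250-bp window per hDel, planted effects on
    the named hDel indices. Returns (manifest, hdels, counts, planted ids)."""
    rows_h, rows_m = [], []
    for i in range(n_hdels):
        start = i * 1000
        rows_h.append(("chr1", start, start + 250, f"h{i:04d}"))
        for j in range(guides_per_hdel):
            s = start + 12 + j * (226 // guides_per_hdel)
            rows_m.append(
                (f"h{i:04d}_g{j}", "G" * 20, "hdel", "chr1", s, s + 20, f"h{i:04d}")
            )
    hdels = pd.DataFrame(rows_h, columns=["chrom", "start", "end", "name"])
    man = pd.DataFrame(
        rows_m, columns=["id", "spacer", "category", "chrom", "start", "end", "hdel_id"]
    )
    hix = hdels.set_index("name")
    planted_ids = [f"h{i:04d}" for i in planted]
    intervals = [
        (GenomicInterval("chr1", int(hix.loc[h, "start"]), int(hix.loc[h, "end"])), lfc)
        for h in planted_ids
    ]
    truth = syn.make_screen_truth(
        man, planted=intervals, depth=depth, dispersion=dispersion,
        n_replicates=n_replicates, n_individuals=n_individuals, seed=seed,
    )
    counts = syn.simulate_screen(man, truth, seed=seed + 1)
    return man, hdels, counts, planted_ids
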