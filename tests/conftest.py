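import numpy as np
import pandas as pd
import pytest

from tfinet import simulate as sim


@pytest.fixture(scope="session")
def small_experiment():
    """A 120-gene synthetic probe-level experiment with default noise."""
    cfg = sim.SimConfig(n_genes=120, seed=11)
    design = sim.make_default_design()
    probes, probe_map, truth = sim.generate_expression_experiment(cfg, design)
    return cfg, design, probes, probe_map, truth


@pytest.fixture(scope="session")
def chip_fixture():
    """Annotation + planted ChIP experiment with 6 TFs and a full triad."""
    ann = sim.generate_annotation(2, 2_000_000, 60, seed=7, min_gap=12_000)
    names = list(ann["name"])
    rng = np.random.default_rng(3)
    tf_genes = names[:6]
    specs = {}
    for i in range(6):
        targets = set(rng.choice(names[6:], size=12, replace=False))
        if i < 3:
            targets |= set(tf_genes[:3])
        specs[f"TF{i + 1}"] = sim.TFSpec(gene=tf_genes[i],
                                         targets=tuple(sorted(targets)))
    peaks, reads, inp, truth = sim.generate_chip_experiment(ann, specs, seed=11)
    return ann, specs, peaks, reads, inp, truth


def random_bed(rng, n, chroms=("chr1", "chr2"), span=100_000, width=(50, 3000)):
    """Random interval frame for brute-force oracle comparisons."""
    ci = rng.integers(0, len(chroms), size=n)
    starts = rng.integers(0, span, size=n)
    widths = rng.integers(width[0], width[1], size=n)
    return pd.DataFrame({
        "chrom": [chroms[i] for i in ci],
        "start": starts,
        "end": starts + widths,
        "name": [f"iv{i}" for i in range(n)],
        "score": 0.0,
        "strand": ".",
    })
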