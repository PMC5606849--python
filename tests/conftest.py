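import numpy as np
import pandas as pd
import pytest

from vertebrome import (
    MEASURES,
    PhantomSpec,
    Phenome,
    assemble_phenome,
    binarize,
    generate_spine_phantom,
    segment_elements,
    separate_vertebrae,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless 3-vertebra phantom with ground truth (cheap, exact)."""
    spec = PhantomSpec(n_vertebrae=3, noise_sd=0.0, seed=1)
    return generate_spine_phantom(spec)


@pytest.fixture(scope="session")
def small_pipeline(small_phantom):
    """Full segmentation + morphometry products of the noiseless phantom."""
    vol, truth = small_phantom
    mask = binarize(vol, truth.suggested_threshold)
    labelmap = separate_vertebrae(mask, truth.seed_lines)
    seeds = sorted(truth.seed_lines, key=lambda s: s.ap_midpoint)
    elements = {
        v: segment_elements(labelmap.vertebra_mask(v), seeds[v - 1], seeds[v])
        for v in range(1, labelmap.n_vertebrae + 1)
    }
    phenome = assemble_phenome(
        elements, vol, seeds, fish_id="phantom0", standard_length=24.0,
        group="control",
    )
    return {
        "vol": vol,
        "truth": truth,
        "mask": mask,
        "labelmap": labelmap,
        "elements": elements,
        "phenome": phenome,
        "seeds": seeds,
    }


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default 5-vertebra phantom with Gaussian noise."""
    return generate_spine_phantom(PhantomSpec(seed=7))


def make_phenome(
    fish_id,
    values: dict[str, np.ndarray],
    n_vertebrae: int = 16,
    standard_length: float | None = 24.0,
    group: str | None = None,
    fill: float = 1.0,
) -> Phenome:
    """Synthetic phenome: given feature columns, remaining measures constant."""
    table = pd.DataFrame(
        fill, index=pd.RangeIndex(1, n_vertebrae + 1, name="vertebra"),
        columns=list(MEASURES),
    )
    for feat, vals in values.items():
        table[feat] = np.asarray(vals, dtype=float)
    return Phenome(
        fish_id=fish_id, table=table, standard_length=standard_length, group=group
    )
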