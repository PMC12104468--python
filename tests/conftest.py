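import numpy as np
import pytest

from slidesurv.graph_construction import (
    GraphConfig,
    SUBTYPES,
    TileRecord,
    build_graph,
)
from slidesurv.survival import SurvivalRecord


def make_tiles(n_rows, n_cols, subtypes=None, tissue=1.0, slide_id="S0"):
    """Grid of tiles with optional per-tile subtype labels (row-major)."""
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            tiles.append(
                TileRecord(
                    slide_id=slide_id,
                    row=r,
                    col=c,
                    center_x=(c + 0.5) * 512.0,
                    center_y=(r + 0.5) * 512.0,
                    tissue_fraction=tissue if np.isscalar(tissue) else tissue[i],
                    subtype=subtypes[i] if subtypes is not None else "non-tumor",
                )
            )
    return tiles


@pytest.fixture
def toy_graph():
    """A 4x3 slide with mixed subtypes and random 8-dim deep features."""
    rng = np.random.default_rng(7)
    subs = [SUBTYPES[i % 6] for i in range(12)]
    tiles = make_tiles(4, 3, subtypes=subs)
    X = rng.standard_normal((12, 8))
    return build_graph(tiles, X, GraphConfig(k=3, pe_dim=16))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_records(times, events):
    return [
        SurvivalRecord(patient_id=f"P{i}", time_days=int(t), event=bool(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]
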