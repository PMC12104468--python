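"""Desk-scale synthetic cohorts of tile graphs with survival outcomes.

Each synthetic patient mimics the structure of an early-stage lung
adenocarcinoma cohort: one to three slides, each a small tile grid whose
tiles carry one of six subtype labels (five growth patterns plus non-tumor)
laid out with spatial autocorrelation, per-tile deep features drawn around
subtype-specific Gaussian centroids, and a right-censored time-to-event
outcome whose hazard increases with the patient's fraction of aggressive
(micropapillary + solid) tiles.

The planted mechanism is deliberately the simplest one a correct model must
recover: event times are exponential with rate
``baseline_hazard * exp(effect_size * aggressive_fraction)``, censoring is an
independent exponential capped administratively at five years (1825 days).
Defaults target roughly a 40% event fraction at the default effect size.

Dimensions are scaled down from real cohorts (64 tiles per slide instead of
several hundred, 32 feature channels instead of 1024) so that full training
runs on a desk machine; all knobs live in :class:`CohortConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import graph_construction as gc
from .graph_construction import (
    AGGRESSIVE_SUBTYPES,
    GraphConfig,
    SUBTYPES,
    TileRecord,
    WSIGraph,
    build_graph,
)
from .survival import SurvivalRecord, write_survival_table

ADMIN_CENSOR_DAYS = 1825  # five-year administrative cap

#: per-archetype subtype mixtures (order: acinar, lepidic, micropapillary,
#: non-tumor, papillary, solid).  The indolent archetype is lepidic-rich, the
#: aggressive archetype is solid/micropapillary-rich.
ARCHETYPE_MIXTURES = {
    "indolent": (0.12, 0.50, 0.005, 0.30, 0.07, 0.005),
    "aggressive": (0.06, 0.01, 0.22, 0.05, 0.04, 0.62),
}


@dataclass(frozen=True)
class CohortConfig:
    """Recipe for one synthetic cohort."""

    n_patients: int = 300
    slides_per_patient_probs: tuple[float, ...] = (0.75, 0.20, 0.05)  # P(1), P(2), P(3)
    grid_side: int = 8  # 8x8 = 64 tiles per slide
    d_features: int = 32
    effect_size: float = 2.0  # log-hazard per unit aggressive fraction
    baseline_hazard: float = 1.4e-4  # events/day at aggressive fraction 0
    censor_rate: float = 4.0e-4  # random-censoring events/day
    p_aggressive_archetype: float = 0.5
    smoothing_passes: int = 2
    feature_noise_sd: float = 1.0
    subtype_signal_sd: float = 1.0  # spread of subtype centroids in feature space
    tissue_alpha: float = 8.0  # Beta(alpha, beta) tissue fractions
    tissue_beta: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.slides_per_patient_probs) - 1.0) > 1e-9:
            raise ValueError("slides_per_patient_probs must sum to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


@dataclass
class SyntheticPatient:
    record: SurvivalRecord
    graphs: list[WSIGraph]
    tiles: dict[str, list[TileRecord]]  # slide_id -> pre-filter tile table
    features: dict[str, np.ndarray]  # slide_id -> pre-filter feature rows
    true_aggressive_fraction: float
    true_log_hazard: float


def _subtype_centroids(config: CohortConfig) -> np.ndarray:
    """Cohort-wide Gaussian centroid per subtype, fixed by the master seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC3]))
    return rng.normal(0.0, config.subtype_signal_sd, size=(len(SUBTYPES), config.d_features))


def _smooth_subtypes(grid: np.ndarray, passes: int, rng) -> np.ndarray:
    """Neighbour-majority smoothing so subtypes form contiguous patches."""
    side = grid.shape[0]
    for _ in range(passes):
        new = grid.copy()
        for r in range(side):
            for c in range(side):
                neigh = []
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < side and 0 <= cc < side:
                        neigh.append(grid[rr, cc])
                neigh.append(grid[r, c])
                counts = np.bincount(neigh, minlength=len(SUBTYPES))
                best = np.flatnonzero(counts == counts.max())
                new[r, c] = best[0] if len(best) == 1 else rng.choice(best)
        grid = new
    return grid


def _make_slide(
    slide_id: str, mixture, config: CohortConfig, centroids: np.ndarray, rng
) -> tuple[list[TileRecord], np.ndarray]:
    side = config.grid_side
    codes = rng.choice(len(SUBTYPES), size=(side, side), p=np.asarray(mixture))
    if config.smoothing_passes > 0:
        codes = _smooth_subtypes(codes, config.smoothing_passes, rng)
    tissue = rng.beta(config.tissue_alpha, config.tissue_beta, size=(side, side))
    tiles = []
    feats = []
    for r in range(side):
        for c in range(side):
            code = int(codes[r, c])
            tiles.append(
                TileRecord(
                    slide_id=slide_id,
                    row=r,
                    col=c,
                    center_x=(c + 0.5) * gc.TILE_FOOTPRINT_UM,
                    center_y=(r + 0.5) * gc.TILE_FOOTPRINT_UM,
                    tissue_fraction=float(tissue[r, c]),
                    subtype=SUBTYPES[code],
                )
            )
            feats.append(
                centroids[code]
                + rng.normal(0.0, config.feature_noise_sd, size=config.d_features)
            )
    return tiles, np.asarray(feats)


def simulate_survival(
    true_log_hazard: float, config: CohortConfig, seed: int
) -> tuple[int, bool]:
    """Draw (time_days, event) under proportional hazards with right censoring.

    Event time ~ Exp(rate = exp(true_log_hazard)); censoring is the minimum of
    an independent Exp(censor_rate) draw and the administrative five-year cap.
    """
    rng = np.random.default_rng(seed)
    rate = np.exp(true_log_hazard)
    t_event = rng.exponential(1.0 / rate)
    t_cens = (
        rng.exponential(1.0 / config.censor_rate)
        if config.censor_rate > 0
        else np.inf
    )
    t_cens = min(t_cens, ADMIN_CENSOR_DAYS)
    event = t_event <= t_cens
    time_days = max(1, int(np.ceil(min(t_event, t_cens))))
    return time_days, bool(event)


def generate_patient(
    config: CohortConfig,
    patient_seed: int,
    patient_id: str = "P0",
    graph_config: GraphConfig | None = None,
    centroids: np.ndarray | None = None,
) -> SyntheticPatient:
    """Sample one patient: archetype, slides, graphs, planted outcome."""
    if graph_config is None:
        graph_config = GraphConfig(pe_dim=16)
    if centroids is None:
        centroids = _subtype_centroids(config)
    rng = np.random.default_rng(patient_seed)
    archetype = (
        "aggressive"
        if rng.random() < config.p_aggressive_archetype
        else "indolent"
    )
    mixture = ARCHETYPE_MIXTURES[archetype]
    n_slides = 1 + rng.choice(
        len(config.slides_per_patient_probs), p=np.asarray(config.slides_per_patient_probs)
    )
    tiles: dict[str, list[TileRecord]] = {}
    features: dict[str, np.ndarray] = {}
    graphs: list[WSIGraph] = []
    for s in range(int(n_slides)):
        sid = f"{patient_id}_S{s}"
        t, f = _make_slide(sid, mixture, config, centroids, rng)
        tiles[sid] = t
        features[sid] = f
        graphs.append(build_graph(t, f, graph_config))

    agg_codes = {gc.SUBTYPE_INDEX[s] for s in AGGRESSIVE_SUBTYPES}
    n_nodes = sum(g.n_nodes for g in graphs)
    n_agg = sum(int(np.isin(g.subtypes, list(agg_codes)).sum()) for g in graphs)
    frac = n_agg / n_nodes
    log_hazard = np.log(config.baseline_hazard) + config.effect_size * frac
    time_days, event = simulate_survival(
        log_hazard, config, seed=int(rng.integers(0, 2**31 - 1))
    )
    record = SurvivalRecord(
        patient_id=patient_id, time_days=time_days, event=event, cohort="synthetic"
    )
    return SyntheticPatient(
        record=record,
        graphs=graphs,
        tiles=tiles,
        features=features,
        true_aggressive_fraction=frac,
        true_log_hazard=float(log_hazard),
    )


def generate_cohort(
    config: CohortConfig, graph_config: GraphConfig | None = None
) -> list[SyntheticPatient]:
    """Generate the full in-memory cohort, deterministically from config.seed."""
    centroids = _subtype_centroids(config)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_patients) % (2**31 - 1)
    return [
        generate_patient(
            config,
            patient_seed=int(seeds[i]),
            patient_id=f"P{i:04d}",
            graph_config=graph_config,
            centroids=centroids,
        )
        for i in range(config.n_patients)
    ]


def write_cohort(
    patients: list[SyntheticPatient],
    out_dir,
    config: CohortConfig,
    overwrite: bool = False,
) -> None:
    """Write tile TSV, feature HDF5 and survival TSV plus a manifest."""
    out = Path(out_dir)
    manifest = out / "manifest.json"
    if manifest.exists() and not overwrite:
        raise FileExistsError(f"{out} already holds a cohort; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    all_tiles = [t for p in patients for tiles in p.tiles.values() for t in tiles]
    gc.write_tile_table(all_tiles, out / "tiles.tsv")
    feats = {sid: f for p in patients for sid, f in p.features.items()}
    gc.write_features(feats, out / "features.h5")
    write_survival_table([p.record for p in patients], out / "survival.tsv")
    slide_map = {p.record.patient_id: sorted(p.tiles) for p in patients}
    manifest.write_text(
        json.dumps(
            {
                "format_version": 1,
                "config": asdict(config),
                "patient_slides": slide_map,
                "true_aggressive_fraction": {
                    p.record.patient_id: p.true_aggressive_fraction for p in patients
                },
            },
            indent=2,
            sort_keys=True,
        )
    )


def load_cohort(cohort_dir, graph_config: GraphConfig | None = None):
    """Rebuild graphs from an on-disk cohort; returns (patients_dict, records).

    ``patients_dict`` maps patient_id -> list of WSIGraph; records are the
    survival rows in file order.
    """
    from .survival import read_survival_table

    cohort_dir = Path(cohort_dir)
    if graph_config is None:
        graph_config = GraphConfig(pe_dim=16)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    tiles = gc.read_tile_table(cohort_dir / "tiles.tsv")
    feats = gc.read_features(cohort_dir / "features.h5")
    records = read_survival_table(cohort_dir / "survival.tsv")
    graphs: dict[str, list[WSIGraph]] = {}
    for pid, slide_ids in manifest["patient_slides"].items():
        graphs[pid] = [
            build_graph(tiles[sid], feats[sid], graph_config) for sid in slide_ids
        ]
    return graphs, records
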