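"""Feature-level simulator of a 96-well PKT RNAi screen.

Bypasses imaging: per-track morphometric features are drawn directly from
a multivariate log-normal whose location shifts with each gene's planted
effect (parameter multipliers versus mock).  The output schema is
identical to the image quantifier's feature table, so the whole
normalization / classification / hit-calling stage can be exercised with
known ground truth.  Replicate structure follows the screen design:
2 technical x 2 biological replicate plates per layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..datatypes import (FEATURE_COLUMNS, PlateLayout, Treatment,
                         well_ids_96)

__all__ = ["ScreenSimConfig", "ScreenGroundTruth", "generate_screen_plates"]

#: planted-effect multipliers may target these generative parameters
EFFECT_KEYS = ("net_area", "major_axis", "axial_ratio", "roughness")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study-design and noise parameters of the simulated screen.

    Baseline medians mimic an elongated mesenchymal line on the PKT
    assay's native pixel scale (net area ~1e4 px^2, axial ratio ~1.9,
    roughness ~3), placing mock wells clear of every phenotype-class
    threshold.  Track-level log-scale sds are moderate so that strong
    planted effects reach |Z| > 4 while null wells stay near Z = 0.
    """

    genes: tuple[str, ...] = ()
    planted_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    cell_line: str = "Hs578T"
    n_mock_wells: int = 2
    technical_replicates: int = 2
    biological_replicates: int = 2
    mean_tracks_per_well: float = 40.0
    n_images_per_well: int = 36
    # baseline medians / log-sds of the generative features
    net_area_median: float = 10000.0
    net_area_sdlog: float = 0.15
    major_axis_median: float = 160.0
    major_axis_sdlog: float = 0.12
    axial_ratio_median: float = 1.9
    axial_ratio_sdlog: float = 0.10
    roughness_excess_median: float = 2.2
    roughness_excess_sdlog: float = 0.12
    solidity_logit_mean: float = 1.73   # sigmoid -> ~0.85
    solidity_logit_sd: float = 0.30

    def __post_init__(self) -> None:
        for g, eff in self.planted_effects.items():
            if g not in self.genes:
                raise ValueError(f"planted effect references unknown gene {g!r}")
            bad = set(eff) - set(EFFECT_KEYS)
            if bad:
                raise ValueError(f"unknown effect parameters for {g!r}: {sorted(bad)}")
            for k, m in eff.items():
                if not (m > 0):
                    raise ValueError(f"effect multiplier must be > 0 ({g}.{k})")


@dataclass
class ScreenGroundTruth:
    """Planted truth of a simulated screen run."""

    effects: dict[str, dict[str, float]]
    rng_seed: int
    planted_genes: tuple[str, ...]

    def is_null(self, gene: str) -> bool:
        return gene not in self.effects or not self.effects[gene]


def _draw_well_tracks(rng: np.random.Generator, cfg: ScreenSimConfig,
                      eff: dict[str, float], n_tracks: int) -> dict[str, np.ndarray]:
    m = dict.fromkeys(EFFECT_KEYS, 1.0)
    m.update(eff)
    net = np.exp(rng.normal(math.log(cfg.net_area_median * m["net_area"]),
                            cfg.net_area_sdlog, n_tracks))
    major = np.exp(rng.normal(math.log(cfg.major_axis_median * m["major_axis"]),
                              cfg.major_axis_sdlog, n_tracks))
    axial = np.exp(rng.normal(math.log(cfg.axial_ratio_median * m["axial_ratio"]),
                              cfg.axial_ratio_sdlog, n_tracks))
    axial = np.maximum(axial, 1.0 + 1e-6)
    rough = 1.0 + np.exp(rng.normal(
        math.log(cfg.roughness_excess_median * m["roughness"]),
        cfg.roughness_excess_sdlog, n_tracks))
    sol = 1.0 / (1.0 + np.exp(-rng.normal(cfg.solidity_logit_mean,
                                          cfg.solidity_logit_sd, n_tracks)))
    return {
        "net_area": net,
        "gross_area": net / sol,
        "major_axis": major,
        "minor_axis": major / axial,
        "axial_ratio": axial,
        "roughness": rough,
        "perimeter": np.sqrt(rough * 4.0 * math.pi * net),
        "solidity": sol,
    }


def _build_layouts(cfg: ScreenSimConfig) -> list[PlateLayout]:
    """Chunk genes over plates; column 1 is reserved for mock wells."""
    all_wells = well_ids_96()
    mock_ids = [f"{r}1" for r in "ABCDEFGH"][: cfg.n_mock_wells]
    gene_wells = [w for w in all_wells if w not in mock_ids]
    per_plate = len(gene_wells)
    chunks = [cfg.genes[i:i + per_plate]
              for i in range(0, len(cfg.genes), per_plate)] or [()]
    layouts = []
    for ci, chunk in enumerate(chunks):
        for b in range(1, cfg.biological_replicates + 1):
            for t in range(1, cfg.technical_replicates + 1):
                wells = {w: Treatment("mock", "mock") for w in mock_ids}
                for g, w in zip(chunk, gene_wells):
                    wells[w] = Treatment(g, "smartpool")
                layouts.append(PlateLayout(
                    plate_id=f"P{ci + 1}-T{t}B{b}",
                    wells=wells, replicate=(t, b), cell_line=cfg.cell_line))
    return layouts


def generate_screen_plates(
    config: ScreenSimConfig,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, list[PlateLayout], ScreenGroundTruth]:
    """Simulate the screen: feature tables + layouts + ground truth.

    Per-well random streams are derived from the master seed by
    counter-based ``SeedSequence`` splitting, so any subset of plates is
    reproducible independently of the others.
    """
    cfg = config
    layouts = _build_layouts(cfg)
    if not cfg.genes:
        empty = pd.DataFrame(columns=FEATURE_COLUMNS)
        return empty, [], ScreenGroundTruth({}, rng_seed, ())

    rows = []
    for pi, layout in enumerate(layouts):
        for wi, well_id in enumerate(sorted(layout.wells)):
            treat = layout.wells[well_id]
            rng = np.random.default_rng(
                np.random.SeedSequence(rng_seed, spawn_key=(pi, wi)))
            n_tracks = int(rng.poisson(cfg.mean_tracks_per_well))
            if n_tracks == 0:
                continue
            eff = {} if treat.is_mock else cfg.planted_effects.get(treat.name, {})
            feats = _draw_well_tracks(rng, cfg, eff, n_tracks)
            df = pd.DataFrame(feats)
            df.insert(0, "plate_id", layout.plate_id)
            df.insert(1, "well_id", well_id)
            df.insert(2, "track_id", np.arange(1, n_tracks + 1))
            df["n_cells_in_track"] = 1
            rows.append(df)

    features = (pd.concat(rows, ignore_index=True)[FEATURE_COLUMNS]
                if rows else pd.DataFrame(columns=FEATURE_COLUMNS))
    truth = ScreenGroundTruth(
        effects={g: dict(e) for g, e in cfg.planted_effects.items()},
        rng_seed=rng_seed,
        planted_genes=tuple(cfg.planted_effects),
    )
    return features, layouts, truth
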