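"""Screen normalization, phenotype classification and hit calling.

The analysis contract of the PKT screen:

1. wells with fewer than 10 accepted tracks are excluded;
2. every parameter is normalized per plate to the pooled mock wells as a
   robust Z-score, Z = (median_treatment - median_mock) / (1.4826 * MAD_mock);
3. Z-scores are averaged over the 2 technical x 2 biological replicates;
   knockdowns with < 3 images, or with fewer accepted tracks than the
   cell-line minimum (60 for Hs578T, 150 for MDA-MB-231, summed over
   replicates), are removed;
4. migratory phenotypes are called from fixed raw-value and Z thresholds
   (small / small round / big round / long rough / long smooth);
5. hits are validated by siRNA deconvolution: the SMARTpool and at least
   two of the four single siRNAs must show concordant significant effects.

The module is exposed statsmodels-style: build a :class:`MigrationScreen`
from a feature table plus plate layouts, call :meth:`~MigrationScreen.fit`,
and read estimates and calls off the returned :class:`ScreenResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (PARAMETERS, PHENOTYPE_CLASSES, DeconvolutionResult,
                        PhenotypeCall, PlateLayout)

__all__ = [
    "DegenerateSpreadError", "PhenotypeThresholds", "DEFAULT_THRESHOLDS",
    "TRACK_MINIMA", "MAD_CONSISTENCY",
    "apply_well_qc", "robust_z", "build_well_profiles",
    "aggregate_replicates", "classify_phenotype", "call_primary_hits",
    "pca_phenotypes", "validate_deconvolution",
    "MigrationScreen", "ScreenResults",
]

#: consistency constant making the MAD estimate sigma for normal data
MAD_CONSISTENCY = 1.4826

#: minimum accepted tracks per knockdown (summed over replicates), per line
TRACK_MINIMA = {"Hs578T": 60, "MDA-MB-231": 150}


class DegenerateSpreadError(ValueError):
    """Raised when a mock MAD is zero for some parameter."""


@dataclass(frozen=True)
class PhenotypeThresholds:
    """Printed phenotype-class cut-offs (raw values and Z-scores).

    Raw thresholds apply to replicate-averaged well medians in
    quantifier-native pixel units.
    """

    version: str = "screen-2019-print"
    small_z_net: float = -4.0
    small_round_net: float = 8000.0
    small_round_axial: float = 1.7
    small_round_z_net: float = -1.0
    small_round_z_axial: float = -3.0
    big_round_net: float = 8000.0
    big_round_axial: float = 1.7
    big_round_z_net: float = 1.0
    big_round_z_axial: float = -4.0
    long_rough_axial: float = 2.4
    long_rough_major: float = 200.0
    long_rough_roughness: float = 5.0
    long_rough_z_axial: float = 1.0
    long_rough_z_major: float = 1.0
    long_smooth_axial: float = 2.1
    long_smooth_major: float = 180.0
    long_smooth_roughness: float = 5.0


DEFAULT_THRESHOLDS = PhenotypeThresholds()

_CLASSIFY_KEYS = ("raw_net_area", "raw_axial_ratio", "raw_major_axis",
                  "raw_roughness", "z_net_area", "z_axial_ratio",
                  "z_major_axis")


def apply_well_qc(profiles: pd.DataFrame, min_tracks: int = 10) -> pd.DataFrame:
    """Mark wells with fewer than ``min_tracks`` accepted tracks."""
    out = profiles.copy()
    out["qc_pass"] = out["n_tracks"] >= min_tracks
    return out


def _mock_stats(mock_tracks: pd.DataFrame, parameters: Sequence[str]
                ) -> tuple[pd.Series, pd.Series]:
    med = mock_tracks[list(parameters)].median()
    mad = (mock_tracks[list(parameters)] - med).abs().median()
    return med, mad


def robust_z(treatment_tracks: pd.DataFrame, mock_tracks: pd.DataFrame,
             parameters: Sequence[str] = PARAMETERS) -> pd.Series:
    """Robust Z of a treatment well against the plate's pooled mock tracks.

    Z = (median_treatment - median_mock) / (MAD_CONSISTENCY * MAD_mock),
    computed per parameter on track-level values.
    """
    med_mock, mad_mock = _mock_stats(mock_tracks, parameters)
    zero = mad_mock[mad_mock == 0]
    if len(zero):
        raise DegenerateSpreadError(
            f"mock MAD is zero for parameter(s): {list(zero.index)}")
    med_t = treatment_tracks[list(parameters)].median()
    return (med_t - med_mock) / (MAD_CONSISTENCY * mad_mock)


def build_well_profiles(
    features: pd.DataFrame,
    layouts: Iterable[PlateLayout],
    min_tracks: int = 10,
    n_images: int | Mapping[tuple[str, str], int] = 36,
    parameters: Sequence[str] = PARAMETERS,
) -> pd.DataFrame:
    """Per-well raw medians + robust Z-scores, one row per plate/well.

    Normalization is per plate: each plate's wells are scored against its
    own pooled mock tracks (requires >= 2 mock wells and >= 10 pooled
    mock tracks).
    """
    rows = []
    for layout in layouts:
        plate = features[features["plate_id"] == layout.plate_id]
        mock_ids = layout.mock_wells
        if len(mock_ids) < 2:
            raise ValueError(f"plate {layout.plate_id}: need >= 2 mock wells")
        mock_tracks = plate[plate["well_id"].isin(mock_ids)]
        if len(mock_tracks) < 10:
            raise ValueError(
                f"plate {layout.plate_id}: only {len(mock_tracks)} pooled "
                "mock tracks (>= 10 required)")
        med_mock, mad_mock = _mock_stats(mock_tracks, parameters)
        zero = mad_mock[mad_mock == 0]
        if len(zero):
            raise DegenerateSpreadError(
                f"plate {layout.plate_id}: mock MAD is zero for "
                f"parameter(s): {list(zero.index)}")
        for well_id in sorted(layout.wells):
            treat = layout.wells[well_id]
            tracks = plate[plate["well_id"] == well_id]
            row = {
                "plate_id": layout.plate_id, "well_id": well_id,
                "treatment": treat.name, "kind": treat.kind,
                "technical": layout.replicate[0],
                "biological": layout.replicate[1],
                "cell_line": layout.cell_line,
                "n_tracks": int(len(tracks)),
                "n_images": (n_images if isinstance(n_images, int)
                             else n_images.get((layout.plate_id, well_id), 0)),
            }
            if len(tracks):
                med = tracks[list(parameters)].median()
                for p in parameters:
                    row[f"raw_{p}"] = float(med[p])
                    row[f"z_{p}"] = float(
                        (med[p] - med_mock[p]) / (MAD_CONSISTENCY * mad_mock[p]))
            else:
                for p in parameters:
                    row[f"raw_{p}"] = np.nan
                    row[f"z_{p}"] = np.nan
            rows.append(row)
    profiles = pd.DataFrame(rows)
    return apply_well_qc(profiles, min_tracks=min_tracks)


def aggregate_replicates(
    profiles: pd.DataFrame,
    cell_line: str | None = None,
    min_images: int = 3,
    min_tracks: int | None = None,
    min_replicates: int = 2,
    parameters: Sequence[str] = PARAMETERS,
) -> pd.DataFrame:
    """Average replicate Z-scores per treatment and apply knockdown QC.

    Wells failing per-well QC are dropped before averaging; a treatment
    is excluded when fewer than ``min_replicates`` wells remain, when its
    summed image count is below ``min_images``, or when its summed
    accepted-track count is below the cell-line minimum.
    """
    if min_tracks is None:
        line = cell_line if cell_line is not None else (
            profiles["cell_line"].iloc[0] if len(profiles) else None)
        if line not in TRACK_MINIMA:
            raise ValueError(
                f"no track minimum known for cell line {line!r}; "
                "pass min_tracks explicitly")
        min_tracks = TRACK_MINIMA[line]

    ok = profiles[profiles["qc_pass"]]
    rows = []
    for (name, kind), grp in profiles.groupby(["treatment", "kind"], sort=True):
        passed = grp[grp["qc_pass"]]
        row = {"treatment": name, "kind": kind,
               "n_replicates": int(len(passed)),
               "n_tracks_total": int(passed["n_tracks"].sum()),
               "n_images_total": int(passed["n_images"].sum())}
        for p in parameters:
            row[f"z_{p}"] = float(passed[f"z_{p}"].mean()) if len(passed) else np.nan
            row[f"raw_{p}"] = float(passed[f"raw_{p}"].mean()) if len(passed) else np.nan
        reasons = []
        if len(passed) < min_replicates:
            reasons.append(f"<{min_replicates} replicates")
        if row["n_images_total"] < min_images:
            reasons.append(f"<{min_images} images")
        if row["n_tracks_total"] < min_tracks:
            reasons.append(f"<{min_tracks} tracks")
        row["included"] = not reasons
        row["exclusion_reason"] = "; ".join(reasons)
        rows.append(row)
    return pd.DataFrame(rows)


def classify_phenotype(
    profile: Mapping[str, float],
    thresholds: PhenotypeThresholds = DEFAULT_THRESHOLDS,
) -> PhenotypeCall:
    """Evaluate the five phenotype rule-sets on one aggregated profile.

    All raw-value and Z conditions of a class are conjunctive; the
    primary class is the first match in the listed order (small, small
    round, big round, long rough, long smooth); no match = unclassified.
    """
    missing = [k for k in _CLASSIFY_KEYS if k not in profile]
    if missing:
        raise ValueError(f"profile is missing parameter(s): {missing}")
    vals = {k: float(profile[k]) for k in _CLASSIFY_KEYS}
    if any(math.isnan(v) for v in vals.values()):
        raise ValueError("profile contains NaN parameters")
    t = thresholds
    matches = []
    if vals["z_net_area"] < t.small_z_net:
        matches.append("small")
    if (vals["raw_net_area"] < t.small_round_net
            and vals["raw_axial_ratio"] < t.small_round_axial
            and vals["z_net_area"] < t.small_round_z_net
            and vals["z_axial_ratio"] < t.small_round_z_axial):
        matches.append("small_round")
    if (vals["raw_net_area"] > t.big_round_net
            and vals["raw_axial_ratio"] < t.big_round_axial
            and vals["z_net_area"] > t.big_round_z_net
            and vals["z_axial_ratio"] < t.big_round_z_axial):
        matches.append("big_round")
    if (vals["raw_axial_ratio"] > t.long_rough_axial
            and vals["raw_major_axis"] > t.long_rough_major
            and vals["raw_roughness"] > t.long_rough_roughness
            and vals["z_axial_ratio"] > t.long_rough_z_axial
            and vals["z_major_axis"] > t.long_rough_z_major):
        matches.append("long_rough")
    if (vals["raw_axial_ratio"] > t.long_smooth_axial
            and vals["raw_major_axis"] > t.long_smooth_major
            and vals["raw_roughness"] < t.long_smooth_roughness):
        matches.append("long_smooth")
    primary = matches[0] if matches else "unclassified"
    return PhenotypeCall(primary_class=primary,
                         all_matching_classes=frozenset(matches),
                         thresholds_version=t.version)


def call_primary_hits(
    calls: Mapping[str, pd.DataFrame] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hit table (primary_class != unclassified) and cross-line overlap.

    ``calls`` is either one classification table (columns treatment,
    primary_class) or a mapping cell_line -> table.  The overlap set
    contains genes called with the *same* phenotype class in both lines.
    """
    if isinstance(calls, pd.DataFrame):
        calls = {"": calls}
    hit_frames = []
    for line, df in calls.items():
        hits = df[df["primary_class"] != "unclassified"].copy()
        hits.insert(0, "cell_line", line)
        hit_frames.append(hits)
    hit_table = (pd.concat(hit_frames, ignore_index=True) if hit_frames
                 else pd.DataFrame(columns=["cell_line", "treatment",
                                            "primary_class"]))
    lines = [l for l in calls if l]
    if len(lines) == 2:
        a = hit_table[hit_table["cell_line"] == lines[0]]
        b = hit_table[hit_table["cell_line"] == lines[1]]
        overlap = a.merge(b, on=["treatment", "primary_class"],
                          suffixes=("_a", "_b"))
        overlap = overlap[["treatment", "primary_class"]].drop_duplicates()
    else:
        overlap = pd.DataFrame(columns=["treatment", "primary_class"])
    return hit_table, overlap


def pca_phenotypes(z_matrix: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Column-standardized PCA of the treatments x parameters Z matrix.

    Components are ordered by decreasing explained variance; the sign of
    each component is fixed by making its largest-magnitude loading
    positive.  Constant columns are dropped with a warning.
    """
    from sklearn.decomposition import PCA

    if z_matrix.shape[0] < 2 or z_matrix.shape[1] < 2:
        raise ValueError("need >= 2 treatments and >= 2 parameters")
    if z_matrix.isna().any().any():
        raise ValueError("Z matrix contains missing values")
    sd = z_matrix.std(ddof=0)
    const = sd[sd == 0].index.tolist()
    if const:
        warnings.warn(f"dropping constant column(s): {const}", stacklevel=2)
        z_matrix = z_matrix.drop(columns=const)
        if z_matrix.shape[1] < 2:
            raise ValueError("fewer than 2 varying parameters remain")
        sd = sd.drop(const)
    x = (z_matrix - z_matrix.mean()) / sd
    pca = PCA()
    scores = pca.fit_transform(x.values)
    loadings = pca.components_
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    names = [f"PC{i + 1}" for i in range(loadings.shape[0])]
    return (pd.DataFrame(scores, index=z_matrix.index, columns=names),
            pd.DataFrame(loadings, index=names, columns=z_matrix.columns),
            pca.explained_variance_ratio_)


def validate_deconvolution(
    gene: str,
    pool_z: Mapping[str, float],
    single_z: Sequence[Mapping[str, float] | None],
    parameters: Sequence[str] = ("net_area", "axial_ratio"),
    z_cut: float = 2.0,
) -> DeconvolutionResult:
    """Apply the ">= 2 singles + SMARTpool" validation contract.

    The SMARTpool is significant when |Z| >= z_cut on at least one tested
    parameter.  A single siRNA counts as concordant-significant when
    |Z| >= z_cut on a tested parameter *and* its sign matches the
    SMARTpool's sign on that parameter.  Missing singles count as
    non-significant.
    """
    if len(single_z) != 4:
        raise ValueError("exactly four single-siRNA profiles expected")
    pool_sig = any(abs(float(pool_z[p])) >= z_cut for p in parameters)
    n_sig = 0
    missing = 0
    for s in single_z:
        if s is None:
            missing += 1
            continue
        for p in parameters:
            zs, zp = float(s[p]), float(pool_z[p])
            if abs(zs) >= z_cut and zs * zp > 0:
                n_sig += 1
                break
    return DeconvolutionResult(
        gene=gene,
        pool_z={p: float(pool_z[p]) for p in parameters},
        single_z=[None if s is None else {p: float(s[p]) for p in parameters}
                  for s in single_z],
        n_significant_singles=n_sig,
        valid=bool(pool_sig and n_sig >= 2),
        missing_singles=missing,
    )


# --------------------------------------------------------------------------
# model / results objects


class MigrationScreen:
    """PKT migration screen model: feature table + plate layouts.

    Parameters
    ----------
    features
        Track-level feature table (schema of
        :data:`pktscreen.datatypes.FEATURE_COLUMNS`).
    layouts
        The plate layouts; replicate structure and mock wells are read
        from them.
    cell_line
        Defaults to the layouts' cell line; sets the knockdown
        track-count minimum (60 Hs578T / 150 MDA-MB-231) unless
        ``min_tracks_per_knockdown`` is given.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        layouts: Sequence[PlateLayout],
        cell_line: str | None = None,
        thresholds: PhenotypeThresholds = DEFAULT_THRESHOLDS,
        min_tracks_per_well: int = 10,
        min_images: int = 3,
        min_tracks_per_knockdown: int | None = None,
        n_images_per_well: int | Mapping[tuple[str, str], int] = 36,
        z_cut: float = 2.0,
    ) -> None:
        self.features = features
        self.layouts = list(layouts)
        if not self.layouts:
            raise ValueError("at least one plate layout is required")
        self.cell_line = cell_line or self.layouts[0].cell_line
        self.thresholds = thresholds
        self.min_tracks_per_well = min_tracks_per_well
        self.min_images = min_images
        self.min_tracks_per_knockdown = min_tracks_per_knockdown
        self.n_images_per_well = n_images_per_well
        self.z_cut = z_cut

    @classmethod
    def from_csv(cls, features_csv, layout_files, **kwargs) -> "MigrationScreen":
        from .io import read_features, read_layout
        features = read_features(features_csv)
        layouts = [read_layout(p) for p in layout_files]
        return cls(features, layouts, **kwargs)

    def fit(self) -> "ScreenResults":
        well_profiles = build_well_profiles(
            self.features, self.layouts,
            min_tracks=self.min_tracks_per_well,
            n_images=self.n_images_per_well)
        aggregated = aggregate_replicates(
            well_profiles, cell_line=self.cell_line,
            min_images=self.min_images,
            min_tracks=self.min_tracks_per_knockdown)
        calls = []
        for _, row in aggregated.iterrows():
            if not row["included"] or row["kind"] == "mock":
                call = PhenotypeCall("unclassified", frozenset(),
                                     self.thresholds.version)
            else:
                call = classify_phenotype(row, self.thresholds)
            calls.append({
                "treatment": row["treatment"], "kind": row["kind"],
                "primary_class": call.primary_class,
                "all_matching_classes": ",".join(sorted(call.all_matching_classes)),
                "included": bool(row["included"]),
            })
        call_table = pd.DataFrame(calls)
        return ScreenResults(self, well_profiles, aggregated, call_table)


class ScreenResults:
    """Fitted screen: per-well profiles, aggregated Z, calls and hits."""

    def __init__(self, model: MigrationScreen, well_profiles: pd.DataFrame,
                 aggregated: pd.DataFrame, calls: pd.DataFrame) -> None:
        self.model = model
        self.well_profiles = well_profiles
        self.treatment_profiles = aggregated
        self.calls = calls

    @property
    def hits(self) -> pd.DataFrame:
        pools = self.calls[(self.calls["kind"] == "smartpool")
                           & self.calls["included"]]
        hits, _ = call_primary_hits(
            {self.model.cell_line: pools[["treatment", "primary_class"]]})
        return hits

    def pca(self, parameters: Sequence[str] = PARAMETERS):
        """PCA of included (non-mock) treatment Z profiles."""
        sel = self.treatment_profiles[
            self.treatment_profiles["included"]
            & (self.treatment_profiles["kind"] != "mock")]
        z = sel.set_index("treatment")[[f"z_{p}" for p in parameters]]
        return pca_phenotypes(z)

    def deconvolution(self) -> list[DeconvolutionResult]:
        """Validate every gene carrying SMARTpool + single-siRNA profiles."""
        agg = self.treatment_profiles
        params = ("net_area", "axial_ratio")
        out = []
        pools = agg[(agg["kind"] == "smartpool") & agg["included"]]
        for _, prow in pools.iterrows():
            gene = prow["treatment"]
            singles = []
            any_single = False
            for k in range(1, 5):
                srow = agg[(agg["treatment"] == gene)
                           & (agg["kind"] == f"single_{k}")
                           & agg["included"]]
                if len(srow):
                    singles.append({p: srow.iloc[0][f"z_{p}"] for p in params})
                    any_single = True
                else:
                    singles.append(None)
            if not any_single:
                continue
            out.append(validate_deconvolution(
                gene, {p: prow[f"z_{p}"] for p in params}, singles,
                parameters=params, z_cut=self.model.z_cut))
        return out

    def summary(self) -> str:
        n_wells = len(self.well_profiles)
        n_fail = int((~self.well_profiles["qc_pass"]).sum())
        agg = self.treatment_profiles
        n_treat = int((agg["kind"] != "mock").sum())
        n_excl = int(((agg["kind"] != "mock") & ~agg["included"]).sum())
        lines = [
            "PKT migration screen results",
            "=" * 60,
            f"cell line:            {self.model.cell_line}",
            f"plates:               {len(self.model.layouts)}",
            f"wells:                {n_wells} ({n_fail} failed well QC)",
            f"treatments:           {n_treat} ({n_excl} excluded by knockdown QC)",
            f"thresholds:           {self.model.thresholds.version}",
            "-" * 60,
            "phenotype class counts (SMARTpool, included):",
        ]
        pools = self.calls[(self.calls["kind"] == "smartpool")
                           & self.calls["included"]]
        counts = pools["primary_class"].value_counts()
        for cls in list(PHENOTYPE_CLASSES) + ["unclassified"]:
            lines.append(f"  {cls:<14} {int(counts.get(cls, 0)):>5}")
        lines.append("=" * 60)
        return "\n".join(lines)

    def plot_pca(self, ax=None):
        """Scatter of treatments on the first two PCs, colored by class."""
        import matplotlib.pyplot as plt

        scores, _, evr = self.pca()
        calls = self.calls.set_index("treatment")["primary_class"]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        for cls, grp in scores.groupby(calls.reindex(scores.index)):
            ax.scatter(grp["PC1"], grp["PC2"], s=14, label=str(cls), alpha=0.7)
        ax.set_xlabel(f"PC1 ({evr[0]:.0%} var)")
        ax.set_ylabel(f"PC2 ({evr[1]:.0%} var)")
        ax.legend(fontsize=8)
        return ax
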