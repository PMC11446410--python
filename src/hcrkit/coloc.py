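"""Dual-method spot comparison: counts and directional colocalization.

Given two sets of detected spots (e.g. HCR and smFISH run on the same
sample), two directional statistics are computed: the fraction of A-spots
whose nearest B-spot lies within a matching radius (default 750 nm, strict
``<`` at the boundary), and the symmetric B-near-A fraction. Matching is
neighbor-existence, not one-to-one assignment — each spot may match a spot
already matched in the other direction, which is why the two directions can
differ. Coordinates are nm throughout; anisotropic voxel sizes are applied
at load time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SpotSet",
    "ColocalizationResult",
    "load_spots",
    "colocalize",
    "summarize_samples",
]


@dataclass
class SpotSet:
    """Detected spot coordinates for one sample and one method, in nm."""

    label: str
    coords: np.ndarray  # (n, 3) float, nm
    sample_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.size and not np.all(np.isfinite(self.coords)):
            raise ValueError(f"spot set {self.label!r}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class ColocalizationResult:
    """Directional within-radius counts and fractions for two spot sets."""

    radius_nm: float
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_a_near_b: int
    n_b_near_a: int
    sample_id: str = ""

    @property
    def frac_a_near_b(self) -> float:
        return self.n_a_near_b / self.n_a if self.n_a else float("nan")

    @property
    def frac_b_near_a(self) -> float:
        return self.n_b_near_a / self.n_b if self.n_b else float("nan")


def load_spots(
    path,
    label: str = "",
    voxel_nm: Optional[tuple[float, float, float]] = None,
    sample_id: str = "",
) -> SpotSet:
    """Read a spot table CSV with x, y, z columns.

    ``voxel_nm`` gives per-axis pixel-to-nm scale factors for tables in
    pixel units; omit it when the table is already in nm. Missing columns or
    non-numeric/NaN entries raise with the offending row number (1-based
    data rows).
    """
    df = pd.read_csv(path)
    missing = [c for c in ("x", "y", "z") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; need x,y,z")
    coords = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad = np.where(~np.isfinite(coords).all(axis=1))[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-numeric or NaN coordinate at data row {bad[0] + 1}"
        )
    if voxel_nm is not None:
        coords = coords * np.asarray(voxel_nm, dtype=float)
    return SpotSet(label=label or str(path), coords=coords, sample_id=sample_id)


def colocalize(
    a: SpotSet,
    b: SpotSet,
    radius_nm: float = 750.0,
    strict_less: bool = True,
) -> ColocalizationResult:
    """Directional within-radius colocalization of two spot sets.

    A spot of A is colocalized iff its nearest neighbor in B lies at
    Euclidean distance < ``radius_nm`` (``<=`` when ``strict_less`` is
    False). Both directions are computed in one call; the KD-tree search is
    exact, so counts equal an all-pairs scan. Invariant under permutation of
    spot order.
    """
    if radius_nm <= 0:
        raise ValueError("radius_nm must be > 0")

    def _near_count(query: np.ndarray, ref: np.ndarray) -> int:
        if len(query) == 0 or len(ref) == 0:
            return 0
        dists, _ = cKDTree(ref).query(query, k=1)
        return int(np.sum(dists < radius_nm if strict_less else dists <= radius_nm))

    return ColocalizationResult(
        radius_nm=radius_nm,
        label_a=a.label,
        label_b=b.label,
        n_a=len(a),
        n_b=len(b),
        n_a_near_b=_near_count(a.coords, b.coords),
        n_b_near_a=_near_count(b.coords, a.coords),
        sample_id=a.sample_id or b.sample_id,
    )


def summarize_samples(results: Sequence[ColocalizationResult]) -> pd.DataFrame:
    """Per-label summary over samples: mean counts, fractions, % difference.

    One row per quantity. Mean directional fractions are reported both ways
    the underlying per-sample statistics can be aggregated: averaged per
    sample ("mean_of_samples") and pooled across samples
    ("pooled_counts", sum of near counts over sum of sizes). The relative
    spot-count difference is 100*(mean_n_a - mean_n_b)/mean_n_b, NaN when
    mean_n_b is 0.
    """
    if not results:
        raise ValueError("summarize_samples: no results")
    la, lb = results[0].label_a, results[0].label_b
    n_a = np.array([r.n_a for r in results], float)
    n_b = np.array([r.n_b for r in results], float)
    mean_a, mean_b = n_a.mean(), n_b.mean()
    pct_diff = 100.0 * (mean_a - mean_b) / mean_b if mean_b else float("nan")

    with np.errstate(invalid="ignore"):
        per_sample_ab = np.array([r.frac_a_near_b for r in results], float)
        per_sample_ba = np.array([r.frac_b_near_a for r in results], float)
    sum_near_ab = sum(r.n_a_near_b for r in results)
    sum_near_ba = sum(r.n_b_near_a for r in results)
    rows = [
        ("n_samples", float(len(results))),
        (f"mean_spots_{la}", mean_a),
        (f"mean_spots_{lb}", mean_b),
        (f"pct_more_spots_{la}_vs_{lb}", pct_diff),
        (f"frac_{la}_near_{lb}_mean_of_samples", np.nanmean(per_sample_ab)),
        (f"frac_{lb}_near_{la}_mean_of_samples", np.nanmean(per_sample_ba)),
        (
            f"frac_{la}_near_{lb}_pooled_counts",
            sum_near_ab / n_a.sum() if n_a.sum() else float("nan"),
        ),
        (
            f"frac_{lb}_near_{la}_pooled_counts",
            sum_near_ba / n_b.sum() if n_b.sum() else float("nan"),
        ),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value"]).set_index("quantity")
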