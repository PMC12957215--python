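"""FISH micrograph quantification: segmentation, cell typing, distances.

Workflow: per-channel intensity thresholding produces binary masks;
8-connected components below a size cutoff are discarded as noise;
surviving components yield intensity-weighted centroids.  DAPI components
are nucleus candidates; a marker is assigned to a nucleus when a spot
centroid from that marker's channel lies within the typing radius
(macrophage markers: 20 um diameter, T-cell markers: 10 um diameter,
boundary inclusive).  Tumor cells come exclusively from the tumor
channel.  Distances are Euclidean in um; the per-cell nearest-tumor
distance is the minimum over tumor centroids, and per-type medians
summarize spatial organization (e.g. how tightly SPP1+ macrophages hug
tumor cells compared with cytotoxic T cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .containers import FishScene

# marker gene -> (lineage class, role). Lineage markers identify the cell
# class; subtype markers refine it; a nucleus carrying both is
# double-positive for that class.
DEFAULT_MARKER_CLASSES: dict[str, tuple[str, str]] = {
    "Clec4f": ("macrophage", "lineage"),
    "C1qa": ("macrophage", "subtype"),
    "Cxcl3": ("macrophage", "subtype"),
    "Cxcl10": ("macrophage", "subtype"),
    "Trem2": ("macrophage", "subtype"),
    "Spp1": ("macrophage", "subtype"),
    "Cd3": ("tcell", "lineage"),
    "Klf2": ("tcell", "subtype"),
}


@dataclass
class Component:
    component_id: int
    centroid_xy: tuple[float, float]  # pixels, (x=col, y=row)
    area: int


@dataclass
class CellCall:
    centroid_um: tuple[float, float]
    nucleus_component_id: int
    assigned_markers: list[tuple[str, float]] = field(default_factory=list)
    resolved_type: str = "unassigned"
    double_positive_classes: tuple[str, ...] = ()

    @property
    def double_positive(self) -> bool:
        return bool(self.double_positive_classes)


@dataclass
class DistanceReport:
    pairwise_um: np.ndarray
    nearest_tumor_um: pd.Series | None
    median_by_type: pd.Series | None
    double_positive_pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["class", "subtype_call", "lineage_call", "distance_um"]
        )
    )


def segment_channel(
    raster: np.ndarray,
    threshold: float | None = None,
    min_component_px: int = 5,
) -> list[Component]:
    """Threshold, 8-connected label, size-filter, weighted centroids.

    ``threshold=None`` uses Otsu's method on the raster.  Components with
    area < min_component_px are discarded.  An empty mask yields an empty
    list, not an error.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2:
        raise ValueError("raster must be 2-D")
    if threshold is None:
        if raster.max() == raster.min():
            return []
        threshold = threshold_otsu(raster)
    mask = raster > threshold
    if not mask.any():
        return []
    labels = cc_label(mask, connectivity=2)
    out = []
    for prop in regionprops(labels, intensity_image=raster):
        if prop.area < min_component_px:
            continue
        cy, cx = prop.centroid_weighted
        out.append(Component(prop.label, (float(cx), float(cy)), int(prop.area)))
    return out


def segment_scene(
    scene: FishScene,
    threshold: float | None = None,
    min_component_px: int = 5,
) -> tuple[list[Component], dict[str, list[Component]], list[Component]]:
    """Segment every channel: (nuclei, marker spots per channel, tumor)."""
    nuclei = segment_channel(scene.channels["DAPI"], threshold, min_component_px)
    tumor = (
        segment_channel(scene.channels["tumor"], threshold, min_component_px)
        if "tumor" in scene.channels
        else []
    )
    spots = {
        ch: segment_channel(scene.channels[ch], threshold, min_component_px)
        for ch in scene.channels
        if ch not in ("DAPI", "tumor")
    }
    return nuclei, spots, tumor


def call_cells(
    scene: FishScene,
    nuclei: list[Component],
    spots: dict[str, list[Component]],
    mac_diameter_um: float = 20.0,
    t_diameter_um: float = 10.0,
    marker_classes: dict[str, tuple[str, str]] | None = None,
) -> list[CellCall]:
    """Type each nucleus from marker spots within the class typing radius.

    A marker is assigned when a spot centroid lies within
    diameter/2 of the nucleus centroid (inclusive).  The resolved type is
    the nearest assigned marker's subtype (or bare lineage when only the
    lineage marker hits).  Nuclei carrying both a lineage and a subtype
    marker of one class are flagged double-positive for that class.
    """
    marker_classes = marker_classes or DEFAULT_MARKER_CLASSES
    radius = {"macrophage": mac_diameter_um / 2.0, "tcell": t_diameter_um / 2.0}
    px = scene.pixel_size_um

    for channel in spots:
        marker = scene.channel_map.get(channel)
        if marker is None:
            raise ValueError(f"channel {channel!r} missing from channel_map")
        if marker not in marker_classes:
            raise ValueError(f"marker {marker!r} has no class assignment")

    calls = []
    for nuc in nuclei:
        nx, ny = nuc.centroid_xy
        assigned: list[tuple[str, float]] = []
        for channel, comps in spots.items():
            marker = scene.channel_map[channel]
            cls, _role = marker_classes[marker]
            for spot in comps:
                d_um = float(np.hypot(spot.centroid_xy[0] - nx,
                                      spot.centroid_xy[1] - ny)) * px
                if d_um <= radius[cls]:
                    assigned.append((marker, d_um))
        call = CellCall(
            centroid_um=(nx * px, ny * px),
            nucleus_component_id=nuc.component_id,
            assigned_markers=sorted(assigned, key=lambda md: md[1]),
        )
        if assigned:
            # the nearest assigned marker decides the class; within that
            # class the nearest *subtype* marker names the cell (a lineage
            # marker alone yields the bare class)
            cls, _ = marker_classes[call.assigned_markers[0][0]]
            base = "Mac" if cls == "macrophage" else "T"
            subtype = next(
                (m for m, _ in call.assigned_markers
                 if marker_classes[m] == (cls, "subtype")),
                None,
            )
            call.resolved_type = f"{subtype}+ {base}" if subtype else base
            dp = []
            for cls_name in ("macrophage", "tcell"):
                roles = {
                    marker_classes[m][1]
                    for m, _ in assigned
                    if marker_classes[m][0] == cls_name
                }
                if {"lineage", "subtype"} <= roles:
                    dp.append(cls_name)
            call.double_positive_classes = tuple(dp)
        calls.append(call)
    return calls


def tumor_calls_from(tumor_components: list[Component], pixel_size_um: float
                     ) -> list[CellCall]:
    return [
        CellCall(
            centroid_um=(c.centroid_xy[0] * pixel_size_um,
                         c.centroid_xy[1] * pixel_size_um),
            nucleus_component_id=c.component_id,
            resolved_type="tumor",
        )
        for c in tumor_components
    ]


def _double_positive_pairs(
    calls: list[CellCall],
    marker_classes: dict[str, tuple[str, str]],
    radius: dict[str, float],
) -> pd.DataFrame:
    """Pair each subtype-marker call with the nearest same-class lineage call.

    A nucleus carrying both markers pairs with itself at distance 0.
    """
    rows = []
    for i, call in enumerate(calls):
        for cls in call.double_positive_classes:
            rows.append({"class": cls, "subtype_call": i, "lineage_call": i,
                         "distance_um": 0.0})
    # cross-nucleus pairs: subtype-only call near a lineage-only call
    for cls in ("macrophage", "tcell"):
        sub_idx = [
            i for i, c in enumerate(calls)
            if cls not in c.double_positive_classes
            and any(marker_classes[m] == (cls, "subtype")
                    for m, _ in c.assigned_markers)
        ]
        lin_idx = [
            i for i, c in enumerate(calls)
            if any(marker_classes[m] == (cls, "lineage")
                   for m, _ in c.assigned_markers)
        ]
        for i in sub_idx:
            best = None
            for j in lin_idx:
                if i == j:
                    continue
                d = float(np.hypot(
                    calls[i].centroid_um[0] - calls[j].centroid_um[0],
                    calls[i].centroid_um[1] - calls[j].centroid_um[1],
                ))
                if d <= radius[cls] and (best is None or d < best[1]):
                    best = (j, d)
            if best is not None:
                rows.append({"class": cls, "subtype_call": i,
                             "lineage_call": best[0], "distance_um": best[1]})
    return pd.DataFrame(
        rows, columns=["class", "subtype_call", "lineage_call", "distance_um"]
    )


def distance_report(
    calls: list[CellCall],
    tumor_calls: list[CellCall],
    mac_diameter_um: float = 20.0,
    t_diameter_um: float = 10.0,
    marker_classes: dict[str, tuple[str, str]] | None = None,
) -> DistanceReport:
    """Pairwise and nearest-tumor distance statistics in um."""
    marker_classes = marker_classes or DEFAULT_MARKER_CLASSES
    coords = np.array([c.centroid_um for c in calls], dtype=float).reshape(-1, 2)
    pairwise = cdist(coords, coords) if len(coords) else np.zeros((0, 0))

    nearest = median_by_type = None
    if tumor_calls:
        tumor_xy = np.array([c.centroid_um for c in tumor_calls], dtype=float)
        if len(coords):
            d = cdist(coords, tumor_xy).min(axis=1)
            types = [c.resolved_type for c in calls]
            nearest = pd.Series(d, name="nearest_tumor_um")
            median_by_type = (
                pd.DataFrame({"type": types, "d": d})
                .groupby("type")["d"].median()
                .rename("median_nearest_tumor_um")
            )
    else:
        warnings.warn("no tumor calls; nearest-tumor statistics omitted",
                      stacklevel=2)

    radius = {"macrophage": mac_diameter_um / 2.0, "tcell": t_diameter_um / 2.0}
    dp = _double_positive_pairs(calls, marker_classes, radius)
    return DistanceReport(
        pairwise_um=pairwise,
        nearest_tumor_um=nearest,
        median_by_type=median_by_type,
        double_positive_pairs=dp,
    )


def quantify_scene(
    scene: FishScene,
    threshold: float | None = None,
    min_component_px: int = 5,
    mac_diameter_um: float = 20.0,
    t_diameter_um: float = 10.0,
    marker_classes: dict[str, tuple[str, str]] | None = None,
) -> tuple[list[CellCall], list[CellCall], DistanceReport]:
    """End-to-end: segment all channels, type cells, compute distances."""
    nuclei, spots, tumor_comps = segment_scene(scene, threshold, min_component_px)
    calls = call_cells(scene, nuclei, spots, mac_diameter_um, t_diameter_um,
                       marker_classes)
    tumors = tumor_calls_from(tumor_comps, scene.pixel_size_um)
    report = distance_report(calls, tumors, mac_diameter_um, t_diameter_um,
                             marker_classes)
    return calls, tumors, report
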