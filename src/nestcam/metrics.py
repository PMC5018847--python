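"""Per-clutch camouflage metrics.

Three families of measures, all computed from the CIELAB scene, the
three-region decomposition and a Canny edge map:

* pattern-complexity matching — BgEdge, EggEdge and their ratio CompRat
  (internal egg edge density over substrate edge density; best matching
  near 1);
* disruptive effects — ContEdge (edge density in the 12-px contour band),
  DisRat = ContEdge/EggEdge (outline conspicuousness relative to internal
  egg patterning) and VisRat = ContEdge/BgEdge (relative to the substrate);
* background color matching — DeltaE (CIE76 distance between mean clutch
  color and mean substrate color) and PropBgToEggColorMatch (fraction of
  substrate pixels within one clutch standard deviation of the clutch mean
  on every CIELAB channel).

Ratios with zero denominators are missing (NaN), never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .color import ColorTriple, LabScene, delta_e
from .edges import EdgeMap, edge_proportion
from .regions import RegionSet

logger = logging.getLogger(__name__)

#: Column order of the per-nest metrics CSV.
METRIC_COLUMNS = [
    "BgEdge",
    "EggEdge",
    "ContEdge",
    "CompRat",
    "DisRat",
    "VisRat",
    "DeltaE",
    "PropBgToEggColorMatch",
    "PropMaculation",
]


@dataclass
class CamouflageRecord:
    """The per-clutch metric vector."""

    nest_id: str = ""
    species: str = ""
    BgEdge: float = np.nan
    EggEdge: float = np.nan
    ContEdge: float = np.nan
    CompRat: float = np.nan
    DisRat: float = np.nan
    VisRat: float = np.nan
    DeltaE: float = np.nan
    PropBgToEggColorMatch: float = np.nan
    PropMaculation: float = np.nan
    mean_egg_color: ColorTriple | None = None
    egg_background_color: ColorTriple | None = None
    maculation_color: ColorTriple | None = None
    substrate_color: ColorTriple | None = None
    maculation_low_confidence: bool = False
    detector_params: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        """Flat dict for a metrics-table row."""
        row = {"nest_id": self.nest_id, "species": self.species}
        row.update({c: getattr(self, c) for c in METRIC_COLUMNS})
        for name, trip in (
            ("egg", self.mean_egg_color),
            ("eggbg", self.egg_background_color),
            ("macul", self.maculation_color),
            ("substrate", self.substrate_color),
        ):
            for ch in ("L", "a", "b"):
                row[f"{name}_{ch}"] = getattr(trip, ch) if trip is not None else np.nan
        row["maculation_low_confidence"] = self.maculation_low_confidence
        row.update(self.detector_params)
        return row


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's threshold evaluated exactly on the sampled values.

    Maximizes the between-class variance over every split between
    consecutive distinct values (no histogram binning, so nearly discrete
    luminance distributions are classed correctly) and returns the
    midpoint of the optimal split; the dark class is ``values < threshold``.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    n = v.size
    if n < 2 or v[0] == v[-1]:
        raise ValueError("need at least two distinct values")
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.arange(1, n)  # dark class = first k samples
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    w0 = k / n
    var_between = w0 * (1 - w0) * (mu0 - mu1) ** 2
    var_between[v[1:] == v[:-1]] = -np.inf  # splits inside a tie are invalid
    best = int(np.argmax(var_between))
    return float((v[best] + v[best + 1]) / 2.0)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if not np.isfinite(den) or den == 0 or not np.isfinite(num):
        logger.info("%s undefined (denominator %s); recorded as missing", name, den)
        return np.nan
    return num / den


def edge_metrics(edge_map: EdgeMap, regions: RegionSet) -> dict:
    """Edge densities per region and their camouflage ratios.

    VisRat is a ratio of *proportions* (not raw counts), so regions of
    different sizes are comparable across photographs; the identity
    VisRat = DisRat * CompRat holds exactly whenever all three are defined.
    """
    out: dict = {}
    for key, region, label in (
        ("BgEdge", regions.background, "background"),
        ("EggEdge", regions.internal, "internal"),
        ("ContEdge", regions.contour_band, "contour band"),
    ):
        try:
            out[key] = edge_proportion(edge_map, region)
        except ValueError:
            logger.warning("empty %s region: %s missing", label, key)
            out[key] = np.nan
    out["CompRat"] = _safe_ratio(out["EggEdge"], out["BgEdge"], "CompRat")
    out["DisRat"] = _safe_ratio(out["ContEdge"], out["EggEdge"], "DisRat")
    out["VisRat"] = _safe_ratio(out["ContEdge"], out["BgEdge"], "VisRat")
    return out


def segment_maculation(
    scene: LabScene,
    internal: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    bimodality_min_separation: float = 1.0,
) -> tuple[np.ndarray, float, bool]:
    """Split internal egg pixels into dark maculation and light egg background.

    Default is Otsu's threshold on the luminance of internal pixels; the
    darker class is maculation (eggshell pigment is darker than the base
    color).  Returns (maculation mask over the full raster,
    prop_maculation, low_confidence flag).  The flag is raised when the
    two classes are barely separated (near-unimodal luminance), in which
    case the proportion is still computed but should be interpreted with
    care.
    """
    internal = np.asarray(internal, dtype=bool)
    if not internal.any():
        raise ValueError("internal region is empty")
    lum = scene.L[internal]
    low_confidence = False
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required for method='fixed'")
        thr = fixed_threshold
    elif method == "otsu":
        if np.ptp(lum) == 0:
            # uniform egg: tie-break assigns everything to the dark class
            thr = lum[0] + 1e-12
            low_confidence = True
        else:
            thr = otsu_threshold(lum)
    else:
        raise ValueError(f"unknown maculation segmentation method {method!r}")
    dark = lum < thr
    if 0 < dark.sum() < dark.size:
        sep = lum[~dark].mean() - lum[dark].mean()
        if sep < bimodality_min_separation:
            low_confidence = True
    elif method == "otsu":
        low_confidence = True
    macul = np.zeros(scene.shape, dtype=bool)
    macul[internal] = dark
    prop = float(dark.sum()) / dark.size
    if low_confidence:
        logger.warning("maculation segmentation low-confidence (weakly bimodal luminance)")
    return macul, prop, low_confidence


def _mean_color(scene: LabScene, sel: np.ndarray) -> ColorTriple | None:
    if not sel.any():
        return None
    return ColorTriple(
        float(scene.L[sel].mean()), float(scene.a[sel].mean()), float(scene.b[sel].mean())
    )


def color_metrics(scene: LabScene, regions: RegionSet, maculation: np.ndarray) -> dict:
    """Mean region colors, DeltaE, and the substrate color-match proportion.

    Clutch color statistics pool egg background and maculation pixels
    (the whole internal region).  PropBgToEggColorMatch counts substrate
    pixels whose L, a and b each fall within one clutch standard deviation
    of the corresponding clutch channel mean; a zero-variance channel
    degenerates to exact equality on that channel (logged).
    """
    maculation = np.asarray(maculation, dtype=bool)
    if not regions.background.any():
        raise ValueError("background region is empty")
    internal = regions.internal
    out: dict = {
        "mean_egg_color": _mean_color(scene, internal),
        "egg_background_color": _mean_color(scene, internal & ~maculation),
        "maculation_color": _mean_color(scene, maculation),
        "substrate_color": _mean_color(scene, regions.background),
    }
    if out["mean_egg_color"] is None:
        logger.warning("internal region empty: color metrics missing")
        out.update({"DeltaE": np.nan, "PropBgToEggColorMatch": np.nan})
        return out
    out["DeltaE"] = delta_e(out["mean_egg_color"], out["substrate_color"])

    bg = regions.background
    match = np.ones(int(bg.sum()), dtype=bool)
    for name, chan in (("L", scene.L), ("a", scene.a), ("b", scene.b)):
        vals = chan[internal]
        mu, sd = float(vals.mean()), float(vals.std())
        if sd == 0:
            logger.info("zero clutch variance on channel %s: exact-match criterion", name)
        match &= np.abs(chan[bg] - mu) <= sd
    out["PropBgToEggColorMatch"] = float(match.sum()) / match.size
    return out


def measure_clutch(
    scene: LabScene,
    regions: RegionSet,
    edge_map: EdgeMap,
    nest_id: str = "",
    species: str = "",
    maculation_method: str = "otsu",
    fixed_threshold: float | None = None,
) -> CamouflageRecord:
    """Compute the full camouflage record for one clutch scene."""
    rec = CamouflageRecord(nest_id=nest_id, species=species)
    for k, v in edge_metrics(edge_map, regions).items():
        setattr(rec, k, v)
    if regions.internal.any():
        macul, prop, lowconf = segment_maculation(
            scene, regions.internal, method=maculation_method, fixed_threshold=fixed_threshold
        )
        rec.PropMaculation = prop
        rec.maculation_low_confidence = lowconf
    else:
        macul = np.zeros(scene.shape, dtype=bool)
    for k, v in color_metrics(scene, regions, macul).items():
        setattr(rec, k, v)
    rec.detector_params = {
        "canny_sigma": edge_map.sigma,
        "canny_high": edge_map.high_threshold,
        "canny_low": edge_map.low_threshold,
        "erode_px": regions.erode_px,
        "dilate_px": regions.dilate_px,
    }
    return rec


def records_to_frame(records) -> "pandas.DataFrame":  # noqa: F821
    """Assemble CamouflageRecords into the per-nest metrics table."""
    import pandas as pd

    return pd.DataFrame([r.as_row() for r in records])
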