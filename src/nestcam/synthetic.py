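"""Synthetic nest scenes and clutch-fate tables with known ground truth.

No image or fate data accompanied the original field study, so every
downstream stage is validated against scenes and survival tables generated
here.  The scene generator emulates the statistical structure of a nest
photograph: a textured ground substrate (disk "spots" of tunable density
and luminance contrast, controlling background edge density), two or three
maculated egg ellipses (tunable base color, speckle density and
egg-to-substrate color offset), rendered in CIELAB and exported as a
calibrated sRGB scene plus clutch mask.  The fate generator draws
exponential predation times whose hazard depends on species and camouflage
covariates, observed only at simulated nest checks every 3-4 days and
censored by a 25-day incubation period — the same observation scheme the
analysis stage assumes for field data.

Scenes are deliberately flat-lit (no 3-D shading or shadows); what passing
tests show is that the measurement and inference machinery is correct, not
that it is robust to photographic nuisance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .color import ColorTriple, LabScene, RgbScene, lab_scene_to_rgb
from .regions import ClutchMask

DEFAULT_ROI_PX = 500
DEFAULT_PIXELS_PER_CM = 37.6  # 500 px across a 13.3 cm crop


@dataclass
class SceneTruth:
    """Ground-truth knobs for one rendered nest scene.

    Densities are expected counts per square centimeter; contrasts are in
    CIELAB L* units.  ``egg_substrate_offset`` is (egg - substrate) in
    CIELAB, so a zero offset renders eggs on a substrate of identical base
    color.
    """

    substrate_spot_density: float = 1.8
    substrate_contrast: float = 20.0
    substrate_spot_radius_px: int = 11
    substrate_spot_ab: tuple = (-4.0, -11.0)
    egg_base_color: ColorTriple = field(default_factory=lambda: ColorTriple(65.0, 4.0, 18.0))
    speckle_density: float = 4.5
    speckle_radius_px: int = 4
    maculation_contrast: float = 28.0
    maculation_ab: tuple = (-5.0, -6.0)
    egg_substrate_offset: ColorTriple = field(default_factory=lambda: ColorTriple(-16.0, -5.0, -12.0))
    n_eggs: int = 3
    seed: int = 0
    roi_px: int = DEFAULT_ROI_PX
    pixels_per_cm: float = DEFAULT_PIXELS_PER_CM

    def __post_init__(self) -> None:
        if self.substrate_spot_density < 0 or self.speckle_density < 0:
            raise ValueError("densities must be non-negative")
        if self.n_eggs not in (2, 3):
            raise ValueError("clutches contain 2 or 3 eggs")
        if self.roi_px < 1 or self.pixels_per_cm <= 0:
            raise ValueError("invalid scene geometry")


def _stamp_disks(channels: list, centers: np.ndarray, radius: int, deltas: list) -> None:
    """Add per-channel ``deltas`` inside disks at ``centers`` (in place).

    Overlapping disks do not compound: each channel shifts pixels covered
    by at least one disk exactly once.
    """
    if len(centers) == 0:
        return
    H, W = channels[0].shape
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = (yy**2 + xx**2) <= radius**2
    covered = np.zeros((H, W), dtype=bool)
    for r, c in centers:
        r0, r1 = max(0, r - radius), min(H, r + radius + 1)
        c0, c1 = max(0, c - radius), min(W, c + radius + 1)
        d = disk[r0 - (r - radius) : r1 - (r - radius), c0 - (c - radius) : c1 - (c - radius)]
        covered[r0:r1, c0:c1] |= d
    for chan, delta in zip(channels, deltas):
        chan[covered] += delta


def _egg_centers(n_eggs: int, roi: int, spacing: float) -> list[tuple[float, float]]:
    """Arrange egg centers around the ROI center, clutch-style."""
    c = roi / 2.0
    if n_eggs == 2:
        return [(c, c - spacing / 2), (c, c + spacing / 2)]
    # 3 eggs: triangle
    r = spacing / np.sqrt(3)
    return [
        (c - r, c),
        (c + r / 2, c - spacing / 2),
        (c + r / 2, c + spacing / 2),
    ]


def make_scene(truth: SceneTruth) -> tuple[RgbScene, ClutchMask, SceneTruth]:
    """Render a nest scene: (sRGB scene, clutch mask, truth echoed back).

    Deterministic given ``truth.seed``.  Eggs are ellipses roughly 3.0 x
    2.2 cm; speckles and substrate spots share the same dark-disk
    primitive so their density knobs steer internal and background edge
    density comparably.
    """
    rng = np.random.default_rng(truth.seed)
    roi = truth.roi_px
    ppcm = truth.pixels_per_cm
    area_cm2 = (roi / ppcm) ** 2

    egg = truth.egg_base_color
    off = truth.egg_substrate_offset
    sub = ColorTriple(egg.L - off.L, egg.a - off.a, egg.b - off.b)

    L = np.full((roi, roi), sub.L, dtype=float)
    a = np.full((roi, roi), sub.a, dtype=float)
    b = np.full((roi, roi), sub.b, dtype=float)

    # substrate texture: dark chromatic disks, Poisson count over the ROI
    n_spots = rng.poisson(truth.substrate_spot_density * area_cm2)
    spot_centers = rng.integers(0, roi, size=(n_spots, 2))
    da, db = truth.substrate_spot_ab
    _stamp_disks(
        [L, a, b], spot_centers, truth.substrate_spot_radius_px,
        [-truth.substrate_contrast, da, db],
    )

    # eggs: ellipses with semi-axes from a nominal 3.0 x 2.2 cm egg
    ax_r = 1.1 * ppcm  # semi-axis across rows
    ax_c = 1.5 * ppcm  # semi-axis across cols (egg length)
    spacing = 2.1 * ppcm
    mask = np.zeros((roi, roi), dtype=bool)
    rows, cols = np.mgrid[0:roi, 0:roi]
    egg_area_cm2 = 0.0
    for (er, ec) in _egg_centers(truth.n_eggs, roi, spacing):
        if er - ax_r < 0 or er + ax_r >= roi or ec - ax_c < 0 or ec + ax_c >= roi:
            raise ValueError("egg ellipse exceeds the ROI")
        inside = ((rows - er) / ax_r) ** 2 + ((cols - ec) / ax_c) ** 2 <= 1.0
        mask |= inside
        egg_area_cm2 += np.pi * (ax_r / ppcm) * (ax_c / ppcm)
    L[mask], a[mask], b[mask] = egg.L, egg.a, egg.b

    # maculation: dark speckles Poisson-placed inside the clutch
    n_speck = rng.poisson(truth.speckle_density * egg_area_cm2)
    if n_speck > 0 and mask.any():
        idx = np.flatnonzero(mask)
        chosen = rng.choice(idx, size=n_speck, replace=True)
        centers = np.column_stack(np.unravel_index(chosen, mask.shape))
        mL, ma, mb = L.copy(), a.copy(), b.copy()
        dma, dmb = truth.maculation_ab
        _stamp_disks(
            [mL, ma, mb], centers, truth.speckle_radius_px,
            [-truth.maculation_contrast, dma, dmb],
        )
        # speckles must not bleed onto the substrate
        for chan, stamped in ((L, mL), (a, ma), (b, mb)):
            chan[mask] = stamped[mask]

    lab = LabScene(L=np.clip(L, 0, 100), a=a, b=b, pixels_per_cm=ppcm)
    rgb = lab_scene_to_rgb(lab, "srgb")
    scene = RgbScene(pixels=rgb, colorspace_tag="srgb", pixels_per_cm=ppcm)
    return scene, ClutchMask(mask), truth


#: Species-level generator settings for a simulated study: plovers lay
#: three-egg clutches on busier, darker-flecked ground and carry denser
#: maculation; terns lay two eggs on barer substrate.
SPECIES_SCENE_SETTINGS = {
    "plover": {"substrate_spot_density": 2.2, "speckle_density": 5.5, "n_eggs": 3},
    "tern": {"substrate_spot_density": 1.4, "speckle_density": 3.0, "n_eggs": 2},
}


def species_scene_truth(species: str, seed: int, **overrides) -> SceneTruth:
    """SceneTruth with the per-species defaults of the simulated study."""
    settings = dict(SPECIES_SCENE_SETTINGS[species])
    settings.update(overrides)
    return SceneTruth(seed=seed, **settings)


@dataclass
class SurvivalTruth:
    """Ground truth of the clutch-fate generator.

    Predation hazard per day for nest i:
        lambda_i = baseline_hazard * exp(beta_species * I[tern]
                                         + sum_m beta_camouflage[m] * x_im)
    Fates are observed at checks every ``check_interval_days`` days and
    censored at ``incubation_days`` (hatching).
    """

    baseline_hazard: float = 0.0075
    beta_species: float = 0.0
    beta_camouflage: dict = field(default_factory=dict)
    incubation_days: int = 25
    check_interval_days: tuple = (3, 4)
    abandonment_prob: float = 0.0

    def __post_init__(self) -> None:
        if not self.baseline_hazard > 0:
            raise ValueError("baseline hazard must be positive")
        if any(d <= 0 for d in self.check_interval_days):
            raise ValueError("check intervals must be positive")


def _visit_schedule(rng: np.random.Generator, truth: SurvivalTruth) -> np.ndarray:
    """Check days 0, ..., capped by a final check at hatching."""
    days = [0]
    while days[-1] < truth.incubation_days:
        days.append(days[-1] + int(rng.choice(truth.check_interval_days)))
    days[-1] = min(days[-1], truth.incubation_days)
    if days[-1] < truth.incubation_days:
        days.append(truth.incubation_days)
    return np.array(days)


def make_survival_table(
    truth: SurvivalTruth,
    covariates: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate nest fates for the rows of ``covariates``.

    ``covariates`` must carry ``species`` (plover/tern) plus every metric
    named in ``truth.beta_camouflage``.  Event times are exponential under
    the log-linear hazard; a predation inside the incubation window is
    recorded at the next scheduled check (detection, not occurrence), so
    recorded event times never exceed the censoring time.  Surviving
    nests are censored at hatching.
    """
    missing = [m for m in truth.beta_camouflage if m not in covariates.columns]
    if missing:
        raise ValueError(f"covariates missing metric columns: {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    for i, (_, cov) in enumerate(covariates.iterrows()):
        lp = truth.beta_species * (1.0 if cov["species"] == "tern" else 0.0)
        for m, beta in truth.beta_camouflage.items():
            lp += beta * float(cov[m])
        lam = truth.baseline_hazard * float(np.exp(lp))
        t = rng.exponential(1.0 / lam)
        visits = _visit_schedule(rng, truth)
        nest_id = cov.get("nest_id", f"nest{i:04d}")
        if t <= truth.incubation_days:
            exit_day = int(visits[np.searchsorted(visits, t)])
            exit_day = max(exit_day, 1)  # a same-day find still spans >0 days
            event, fate = True, "predation"
        elif rng.random() < truth.abandonment_prob:
            attended = visits[visits < truth.incubation_days]
            exit_day = int(attended[-1]) if len(attended) else truth.incubation_days
            exit_day = max(exit_day, 1)
            event, fate = False, "abandonment"
        else:
            exit_day, event, fate = truth.incubation_days, False, "hatched"
        rows.append(
            {
                "nest_id": nest_id,
                "species": cov["species"],
                "entry_day": 0,
                "exit_day": exit_day,
                "event": event,
                "fate_label": fate,
                "true_time": t,
            }
        )
    out = pd.DataFrame(rows)
    keep = [c for c in covariates.columns if c not in out.columns]
    return pd.concat([out.reset_index(drop=True), covariates[keep].reset_index(drop=True)], axis=1)


#: Typical (mean, sd) of each camouflage metric used by the table sampler,
#: in the range reported for plover/tern clutches.
_METRIC_LAWS = {
    "BgEdge": (0.075, 0.012),
    "EggEdge": (0.065, 0.018),
    "ContEdge": (0.085, 0.008),
    "DeltaE": (21.6, 4.6),
    "PropBgToEggColorMatch": (0.4, 0.2),
    "PropMaculation": (0.22, 0.08),
}


def make_null_metric_table(
    n_plover: int = 30,
    n_tern: int = 24,
    seed: int = 0,
    species_shift: dict | None = None,
) -> pd.DataFrame:
    """Draw a per-nest metrics table directly from metric distributions.

    Both species are sampled from the same laws unless ``species_shift``
    maps metric -> additive offset applied to terns; with no shift this is
    the null configuration used for calibration of the comparison stage.
    Derived ratios are computed from the sampled edge densities so the
    algebraic structure of real records is preserved.
    """
    rng = np.random.default_rng(seed)
    shift = species_shift or {}
    n = n_plover + n_tern
    species = np.array(["plover"] * n_plover + ["tern"] * n_tern)
    cols: dict = {"nest_id": [f"nest{i:04d}" for i in range(n)], "species": species}
    for name, (mu, sd) in _METRIC_LAWS.items():
        x = rng.normal(mu, sd, size=n)
        x = x + np.where(species == "tern", shift.get(name, 0.0), 0.0)
        lo = 1e-4
        hi = 1.0 if name != "DeltaE" else np.inf
        cols[name] = np.clip(x, lo, hi)
    df = pd.DataFrame(cols)
    df["CompRat"] = df["EggEdge"] / df["BgEdge"]
    df["DisRat"] = df["ContEdge"] / df["EggEdge"]
    df["VisRat"] = df["ContEdge"] / df["BgEdge"]
    return df


def make_visit_table(
    n_plover: int = 30,
    n_tern: int = 24,
    n_predated_plover: int = 5,
    n_predated_tern: int = 14,
    seed: int = 0,
    incubation_days: int = 25,
) -> pd.DataFrame:
    """Raw nest-check logs with fixed per-species predation counts.

    Produces the long-format visit table the fate-coding stage consumes:
    one row per (nest, visit) with the nest state observed at that check.
    Predated nests are intact up to a random check and found empty at the
    next; surviving nests hatch at the end of incubation.
    """
    if n_predated_plover > n_plover or n_predated_tern > n_tern:
        raise ValueError("predation counts exceed nest counts")
    rng = np.random.default_rng(seed)
    truth = SurvivalTruth(incubation_days=incubation_days)
    rows = []
    k = 0
    for sp, n_sp, n_pred in (("plover", n_plover, n_predated_plover), ("tern", n_tern, n_predated_tern)):
        predated = np.zeros(n_sp, dtype=bool)
        predated[rng.choice(n_sp, size=n_pred, replace=False)] = True
        for j in range(n_sp):
            visits = _visit_schedule(rng, truth)
            nest_id = f"{sp}{k:03d}"
            k += 1
            if predated[j]:
                # found empty at a random check after day 0
                loss_idx = int(rng.integers(1, len(visits)))
                for v in visits[:loss_idx]:
                    rows.append((nest_id, sp, int(v), "intact"))
                rows.append((nest_id, sp, int(visits[loss_idx]), "empty"))
            else:
                for v in visits[:-1]:
                    rows.append((nest_id, sp, int(v), "intact"))
                rows.append((nest_id, sp, int(visits[-1]), "hatched"))
    return pd.DataFrame(rows, columns=["nest_id", "species", "day", "state"])
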