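"""Synthetic-data generators with known ground truth.

Three generators cover the three data modalities of the screening workflow:

* :func:`simulate_screen` — a 384-well primary screen: DMSO + 0% CSE and
  DMSO + 3% CSE control wells plus compound wells at two concentrations x
  three replicates, with planted compound effect classes (inactive,
  swell-restoring, mucus-reducing, toxic, opposite-effect).
* :func:`render_well_image` — multi-channel well images (spheroid dye,
  two mucin channels, nuclei) with exact ground-truth masks.
* :func:`simulate_expression` — a log2-scale gene x sample matrix with
  donor random intercepts, donor-level age/alcohol covariates and a CSE
  effect on a known gene subset.

All generators are deterministic given their seed.

Default study conditions mirror the screening design they emulate: a
301-compound deck at 1 and 10 uM with n = 3 replicate wells, spheroid area
shrinking and luminal MUC5AC rising under 3% CSE, 0%-CSE wells with fewer
spheroids than 3% wells, and 3% wells with lower total nuclear intensity
than 0% wells. Per-well spheroid counts and intensity scales are not
published for this assay and are documented assumptions (see the methods
note), not calibrated values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

from .normalize import ROLE_COMPOUND, ROLE_CONTROL_0, ROLE_CONTROL_3

EFFECT_CLASSES = (
    "inactive",
    "swell_restoring",
    "mucus_reducing",
    "toxic",
    "opposite_effect",
)

PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows x 24 columns = 384 wells


# ---------------------------------------------------------------------------
# Primary screen


@dataclass
class ScreenSimParams:
    """Layout and effect-size parameters for a simulated primary screen.

    Effect sizes are expressed on log2 scale so that 0 always means "no
    effect": a planted swell compound multiplies the well mean area by
    ``2**swell_area_log2fc`` relative to the 3%-CSE condition, a planted
    mucus reducer multiplies the MUC5AC ratio by ``2**mucus_log2fc``, and
    toxic compounds multiply spheroid counts and nuclear intensity by
    ``2**toxic_log2_viability`` (while showing the same apparent swell and
    mucus effects, so only the toxicity filters can reject them).
    Opposite-effect compounds swell but *increase* the MUC5AC ratio by
    ``2**opposite_mucin_log2fc``, exercising the cross-readout filter.

    Well noise is additive Gaussian on the readout scale: ``noise_sd``
    holds one absolute SD per readout, applied identically to control and
    compound wells (so planted effects shift the mean without changing
    the noise, and threshold-exceedance probabilities are analytic).
    Counts get additive Gaussian noise of SD ``count_noise_sd`` and are
    rounded to integers. The default area and mucin SDs put the per-plate
    control MADs of the normalized readouts near 0.1.
    """

    n_compounds: int = 301
    concentrations: tuple[float, ...] = (1.0, 10.0)
    replicates_per_condition: int = 3
    n_plates: int | None = None  # None: smallest layout that fits
    plate_rows: int = 16
    plate_cols: int = 24
    controls_per_plate: dict[str, int] = field(
        default_factory=lambda: {ROLE_CONTROL_0: 48, ROLE_CONTROL_3: 48}
    )
    baseline_area_px: float = 1500.0
    cse_area_shrink_factor: float = 0.6
    baseline_mucin_ratio: float = 0.10
    cse_mucin_ratio: float = 0.20
    count_mean_0pct: float = 40.0
    count_mean_3pct: float = 50.0
    nuclear_mean_0pct: float = 1.2e6
    nuclear_mean_3pct: float = 1.0e6
    effect_class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "swell_restoring": 0.05,
            "mucus_reducing": 0.05,
            "toxic": 0.05,
            "opposite_effect": 0.05,
        }
    )
    swell_area_log2fc: float = np.log2(1.5)
    mucus_log2fc: float = -1.0
    toxic_log2_viability: float = -1.0
    opposite_mucin_log2fc: float = 1.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"area": 135.0, "mucin": 0.02, "nuclear": 8e4}
    )
    count_noise_sd: float = 3.0
    row_col_drift: float = 0.0  # optional linear area gradient across columns
    seed: int = 0

    @property
    def wells_per_plate(self) -> int:
        return self.plate_rows * self.plate_cols

    def validate(self) -> None:
        if not 0 < self.cse_area_shrink_factor <= 1:
            raise ValueError("cse_area_shrink_factor must be in (0, 1]")
        fr = self.effect_class_fractions
        unknown = set(fr) - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect classes: {sorted(unknown)}")
        if any(v < 0 for v in fr.values()) or sum(fr.values()) > 1 + 1e-12:
            raise ValueError("effect_class_fractions must be >= 0 and sum to <= 1")
        if any(v < 0 for v in self.noise_sd.values()) or self.count_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        for role in (ROLE_CONTROL_0, ROLE_CONTROL_3):
            if self.controls_per_plate.get(role, 0) < 4:
                raise ValueError(f"need >= 4 {role} wells per plate")
        if self.replicates_per_condition < 1 or self.n_compounds < 1:
            raise ValueError("counts must be positive")

    def wells_per_compound(self) -> int:
        return len(self.concentrations) * self.replicates_per_condition

    def min_plates(self) -> int:
        capacity = self.wells_per_plate - sum(self.controls_per_plate.values())
        if capacity < self.wells_per_compound():
            raise ValueError("plate layout leaves no room for compound wells")
        per_plate = capacity // self.wells_per_compound()
        return -(-self.n_compounds // per_plate)


def _well_address(row: int, col: int) -> str:
    return f"{PLATE_ROWS[row]}{col + 1}"


def _assign_classes(params: ScreenSimParams, rng: np.random.Generator) -> np.ndarray:
    """Planted class per compound (mutually exclusive; remainder inactive)."""
    n = params.n_compounds
    counts = {
        cls: int(round(frac * n))
        for cls, frac in params.effect_class_fractions.items()
    }
    while sum(counts.values()) > n:  # rounding overshoot
        biggest = max(counts, key=counts.get)
        counts[biggest] -= 1
    labels = np.array(
        list(
            itertools.chain.from_iterable(
                [cls] * k for cls, k in counts.items()
            )
        )
        + ["inactive"] * (n - sum(counts.values())),
        dtype=object,
    )
    rng.shuffle(labels)
    return labels


_CLASS_EFFECTS = {
    # (area_log2fc, mucin_log2fc, viability_log2fc) attribute names
    "inactive": (0.0, 0.0, 0.0),
}


def _class_effect(params: ScreenSimParams, cls: str) -> tuple[float, float, float]:
    """(area, mucin, viability) log2 effects for a planted class."""
    if cls == "inactive":
        return 0.0, 0.0, 0.0
    if cls == "swell_restoring":
        return params.swell_area_log2fc, 0.0, 0.0
    if cls == "mucus_reducing":
        return 0.0, params.mucus_log2fc, 0.0
    if cls == "toxic":
        return (
            params.swell_area_log2fc,
            params.mucus_log2fc,
            params.toxic_log2_viability,
        )
    if cls == "opposite_effect":
        return params.swell_area_log2fc, params.opposite_mucin_log2fc, 0.0
    raise ValueError(f"unknown effect class {cls!r}")


def simulate_screen(
    params: ScreenSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate well-level readouts for a primary screen.

    Returns
    -------
    wells : DataFrame
        One row per well: plate, well, role, compound, concentration,
        replicate, mean_area, spheroid_count, mean_mucin_ratio,
        total_nuclear_intensity, manual_exclusion.
    truth : DataFrame
        One row per compound x concentration with the planted
        ``effect_class``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    n_plates = params.min_plates() if params.n_plates is None else params.n_plates
    if n_plates < params.min_plates():
        raise ValueError(
            f"{n_plates} plates cannot hold {params.n_compounds} compounds "
            f"plus controls (need >= {params.min_plates()})"
        )

    classes = _assign_classes(params, rng)
    wpc = params.wells_per_compound()
    capacity = params.wells_per_plate - sum(params.controls_per_plate.values())
    per_plate = capacity // wpc

    rows: list[dict] = []
    compound_idx = 0
    for plate_i in range(n_plates):
        plate = f"P{plate_i + 1:02d}"
        addresses = [
            _well_address(r, c)
            for r in range(params.plate_rows)
            for c in range(params.plate_cols)
        ]
        rng.shuffle(addresses)
        addr_iter = iter(addresses)

        for role, n_ctrl in params.controls_per_plate.items():
            for _ in range(n_ctrl):
                rows.append(
                    {
                        "plate": plate,
                        "well": next(addr_iter),
                        "role": role,
                        "compound": "",
                        "concentration": np.nan,
                        "replicate": 0,
                        "effect_class": "",
                    }
                )
        n_here = min(per_plate, params.n_compounds - compound_idx)
        for _ in range(n_here):
            cid = f"C{compound_idx + 1:03d}"
            for conc in params.concentrations:
                for rep in range(1, params.replicates_per_condition + 1):
                    rows.append(
                        {
                            "plate": plate,
                            "well": next(addr_iter),
                            "role": ROLE_COMPOUND,
                            "compound": cid,
                            "concentration": conc,
                            "replicate": rep,
                            "effect_class": classes[compound_idx],
                        }
                    )
            compound_idx += 1
    wells = pd.DataFrame(rows)

    # --- readouts -----------------------------------------------------------
    cse_area = params.baseline_area_px * params.cse_area_shrink_factor
    is0 = (wells["role"] == ROLE_CONTROL_0).to_numpy()
    is_comp = (wells["role"] == ROLE_COMPOUND).to_numpy()

    area_mu = np.where(is0, params.baseline_area_px, cse_area).astype(float)
    mucin_mu = np.where(
        is0, params.baseline_mucin_ratio, params.cse_mucin_ratio
    ).astype(float)
    count_mu = np.where(is0, params.count_mean_0pct, params.count_mean_3pct).astype(
        float
    )
    nuc_mu = np.where(
        is0, params.nuclear_mean_0pct, params.nuclear_mean_3pct
    ).astype(float)

    eff = np.array(
        [
            _class_effect(params, c) if c else (0.0, 0.0, 0.0)
            for c in wells["effect_class"]
        ]
    )
    area_mu[is_comp] *= 2.0 ** eff[is_comp, 0]
    mucin_mu[is_comp] *= 2.0 ** eff[is_comp, 1]
    count_mu[is_comp] *= 2.0 ** eff[is_comp, 2]
    nuc_mu[is_comp] *= 2.0 ** eff[is_comp, 2]

    if params.row_col_drift:
        col = wells["well"].str[1:].astype(int).to_numpy()
        gradient = 1.0 + params.row_col_drift * (
            (col - 1) / (params.plate_cols - 1) - 0.5
        )
        area_mu *= gradient

    n = len(wells)
    wells["mean_area"] = area_mu + params.noise_sd["area"] * rng.standard_normal(n)
    wells["mean_mucin_ratio"] = np.clip(
        mucin_mu + params.noise_sd["mucin"] * rng.standard_normal(n),
        1e-6,
        None,
    )
    wells["spheroid_count"] = np.clip(
        np.round(count_mu + params.count_noise_sd * rng.standard_normal(n)),
        0,
        None,
    )
    wells["total_nuclear_intensity"] = np.clip(
        nuc_mu + params.noise_sd["nuclear"] * rng.standard_normal(n),
        0,
        None,
    )
    wells["manual_exclusion"] = False

    truth = (
        wells.loc[is_comp, ["compound", "concentration", "effect_class"]]
        .drop_duplicates()
        .sort_values(["compound", "concentration"])
        .reset_index(drop=True)
    )
    wells = wells.drop(columns="effect_class")
    return wells, truth


# ---------------------------------------------------------------------------
# Well images


@dataclass
class SpheroidSpec:
    """One spheroid: a bright ring with a dimmer lumen."""

    center: tuple[float, float]  # (row, col) pixels
    radius: float
    lumen_radius: float
    ring_intensity: float = 200.0
    lumen_intensity: float = 60.0


@dataclass
class MucinClusterSpec:
    """A luminal mucin cluster owned by one spheroid.

    ``area_fraction`` is the cluster area as a fraction of the owner
    spheroid's total area; the rasterized cluster disk must fit inside the
    owner's lumen.
    """

    owner: int
    channel: int  # 0 = MUC5AC, 1 = MUC5B
    area_fraction: float
    intensity: float = 150.0


@dataclass
class WellImageSpec:
    """Specification of a rendered multi-channel well image.

    Channel layout of the rendered stack: 0 spheroid dye, 1 MUC5AC,
    2 MUC5B, 3 nuclei.
    """

    image_shape: tuple[int, int] = (256, 256)
    spheroids: list[SpheroidSpec] = field(default_factory=list)
    mucin_clusters: list[MucinClusterSpec] = field(default_factory=list)
    nuclei_per_spheroid: int = 12
    nucleus_intensity: float = 180.0
    background_level: float = 10.0
    noise_sd: float = 0.0
    no_overlap: bool = True

    n_mucin_channels: int = 2

    def validate(self) -> None:
        h, w = self.image_shape
        for i, s in enumerate(self.spheroids):
            if not 0 < s.lumen_radius < s.radius:
                raise ValueError(f"spheroid {i}: need 0 < lumen_radius < radius")
            r, c = s.center
            if not (s.radius <= r <= h - s.radius and s.radius <= c <= w - s.radius):
                raise ValueError(f"spheroid {i} does not lie fully inside the image")
        if self.no_overlap:
            for i, a in enumerate(self.spheroids):
                for j, b in enumerate(self.spheroids[:i]):
                    d = np.hypot(
                        a.center[0] - b.center[0], a.center[1] - b.center[1]
                    )
                    if d < a.radius + b.radius:
                        raise ValueError(f"spheroids {j} and {i} overlap")
        for k, cl in enumerate(self.mucin_clusters):
            if not 0 <= cl.area_fraction < 1:
                raise ValueError(f"cluster {k}: area_fraction must be in [0, 1)")
            if not 0 <= cl.owner < len(self.spheroids):
                raise ValueError(f"cluster {k}: owner index out of range")
            if not 0 <= cl.channel < self.n_mucin_channels:
                raise ValueError(f"cluster {k}: channel index out of range")
            sph = self.spheroids[cl.owner]
            if np.sqrt(cl.area_fraction) * sph.radius > sph.lumen_radius + 1e-9:
                raise ValueError(
                    f"cluster {k} does not fit inside the lumen of spheroid "
                    f"{cl.owner}"
                )
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("background_level and noise_sd must be >= 0")


def render_well_image(
    spec: WellImageSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize a well image from its specification.

    Returns
    -------
    stack : float ndarray, shape (2 + n_mucin_channels, H, W)
        Channel 0: spheroid dye (bright ring, dim lumen); channels 1..n:
        mucin channels; last channel: punctate nuclei on spheroid rims.
        Background level plus Gaussian noise everywhere.
    labels : int ndarray (H, W)
        Ground-truth spheroid label map (1-based; 0 = background).
    mucin_masks : bool ndarray (n_mucin_channels, H, W)
        Ground-truth mucin cluster masks per channel.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w = spec.image_shape
    n_chan = 2 + spec.n_mucin_channels
    stack = np.full((n_chan, h, w), float(spec.background_level))
    labels = np.zeros((h, w), dtype=np.int32)
    mucin_masks = np.zeros((spec.n_mucin_channels, h, w), dtype=bool)

    for i, s in enumerate(spec.spheroids, start=1):
        rr, cc = _disk(s.center, s.radius, shape=(h, w))
        labels[rr, cc] = i
        stack[0, rr, cc] = s.ring_intensity
        lr, lc = _disk(s.center, s.lumen_radius, shape=(h, w))
        stack[0, lr, lc] = s.lumen_intensity
        # nuclei on the rim
        nuc_r = (s.radius + s.lumen_radius) / 2.0
        for theta in rng.uniform(0, 2 * np.pi, spec.nuclei_per_spheroid):
            cy = s.center[0] + nuc_r * np.sin(theta)
            cx = s.center[1] + nuc_r * np.cos(theta)
            nr, nc = _disk((cy, cx), 1.5, shape=(h, w))
            stack[-1, nr, nc] = spec.nucleus_intensity

    for cl in spec.mucin_clusters:
        s = spec.spheroids[cl.owner]
        r_cluster = np.sqrt(cl.area_fraction) * s.radius
        if r_cluster <= 0:
            continue
        rr, cc = _disk(s.center, r_cluster, shape=(h, w))
        stack[1 + cl.channel, rr, cc] = cl.intensity
        mucin_masks[cl.channel, rr, cc] = True

    if spec.noise_sd > 0:
        stack += rng.normal(0.0, spec.noise_sd, stack.shape)
        np.clip(stack, 0.0, None, out=stack)
    return stack, labels, mucin_masks


def demo_well_spec(
    n_spheroids: int = 4,
    mucin_fraction: float = 0.2,
    image_shape: tuple[int, int] = (256, 256),
    radius: float = 22.0,
    seed: int = 0,
) -> WellImageSpec:
    """A simple non-overlapping well layout on a grid (testing helper)."""
    rng = np.random.default_rng(seed)
    h, w = image_shape
    grid = int(np.ceil(np.sqrt(n_spheroids)))
    centers = []
    for i in range(n_spheroids):
        gy, gx = divmod(i, grid)
        cy = (gy + 0.5) * h / grid + rng.uniform(-3, 3)
        cx = (gx + 0.5) * w / grid + rng.uniform(-3, 3)
        centers.append((cy, cx))
    # lumen wide enough to hold the requested cluster fraction
    lumen_frac = min(0.9, max(0.6, np.sqrt(mucin_fraction) + 0.05))
    spheroids = [
        SpheroidSpec(center=c, radius=radius, lumen_radius=lumen_frac * radius)
        for c in centers
    ]
    clusters = [
        MucinClusterSpec(owner=i, channel=0, area_fraction=mucin_fraction)
        for i in range(n_spheroids)
    ]
    return WellImageSpec(
        image_shape=image_shape, spheroids=spheroids, mucin_clusters=clusters
    )


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionSimParams:
    """Generative model for the donor-structured expression study.

    Per gene g and sample s:
    ``y_gs = mu_g + beta_g * CSE_s + beta_age * age_d + beta_alc * alc_d
    + u_d + eps``, with ``u_d ~ N(0, tau_donor^2)`` and
    ``eps ~ N(0, sigma_resid^2)``; a ``fraction_de`` subset of genes gets
    ``beta_g = +-beta_cse`` (half each sign), the rest 0.
    """

    n_genes: int = 2000
    n_donors: int = 3
    samples_per_donor: int = 12
    weeks_levels: tuple[int, ...] = (1, 2, 3)
    beta_cse: float = 1.5
    fraction_de: float = 0.1
    tau_donor: float = 0.5
    sigma_resid: float = 0.3
    beta_age: float = 0.02
    beta_alcohol: float = 0.3
    age_range: tuple[float, float] = (12.0, 38.0)
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 2:
            raise ValueError(
                "n_donors must be >= 2 (random intercept unidentifiable)"
            )
        if self.tau_donor < 0 or self.sigma_resid < 0:
            raise ValueError("need tau_donor >= 0 and sigma_resid >= 0")
        if not 0 <= self.fraction_de <= 1:
            raise ValueError("fraction_de must be in [0, 1]")
        if self.samples_per_donor < 2 * len(self.weeks_levels):
            raise ValueError(
                "samples_per_donor must cover both CSE doses at every week"
            )


def simulate_expression(params: ExpressionSimParams):
    """Simulate an :class:`~bronchoscreen.expression.ExpressionStudy`.

    Returns the study plus a truth table (gene, beta_cse, is_de).
    """
    from .expression import ExpressionStudy

    params.validate()
    rng = np.random.default_rng(params.seed)

    # sample sheet: per donor, cycle weeks x doses
    cells = list(itertools.product(params.weeks_levels, (0.0, 3.0)))
    sheet_rows = []
    for d in range(params.n_donors):
        donor = f"D{d + 1}"
        age = rng.uniform(*params.age_range)
        alcohol = int(rng.integers(0, 2))
        for k in range(params.samples_per_donor):
            week, dose = cells[k % len(cells)]
            sheet_rows.append(
                {
                    "sample": f"{donor}_W{week}_C{int(dose)}_R{k // len(cells) + 1}",
                    "donor": donor,
                    "age": age,
                    "alcohol": alcohol,
                    "cse": dose,
                    "weeks": week,
                }
            )
    samples = pd.DataFrame(sheet_rows).set_index("sample")

    n_g, n_s = params.n_genes, len(samples)
    genes = [f"G{i + 1:05d}" for i in range(n_g)]
    n_de = int(round(params.fraction_de * n_g))
    beta = np.zeros(n_g)
    de_idx = rng.choice(n_g, size=n_de, replace=False)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    beta[de_idx] = signs * params.beta_cse

    mu = rng.normal(params.baseline_mean, params.baseline_sd, n_g)
    u = rng.normal(0.0, params.tau_donor, (n_g, params.n_donors))
    donor_pos = samples["donor"].str.slice(1).astype(int).to_numpy() - 1

    cse_ind = (samples["cse"].to_numpy() > 0).astype(float)
    fixed = (
        mu[:, None]
        + beta[:, None] * cse_ind[None, :]
        + params.beta_age * samples["age"].to_numpy()[None, :]
        + params.beta_alcohol * samples["alcohol"].to_numpy()[None, :]
    )
    y = (
        fixed
        + u[:, donor_pos]
        + rng.normal(0.0, params.sigma_resid, (n_g, n_s))
    )
    expr = pd.DataFrame(y, index=genes, columns=samples.index)
    truth = pd.DataFrame(
        {"gene": genes, "beta_cse": beta, "is_de": beta != 0.0}
    )
    study = ExpressionStudy(expr=expr, samples=samples)
    return study, truth
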