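"""Synthetic viability plates, microscopy fields and reporter tables.

Every downstream stage of the package is validated against data with known
ground truth, generated here. The generator encodes the mechanisms the
analysis is meant to detect:

* the *true* surviving cell number under a drug follows a constrained
  logistic in concentration, ``N(c) = N0 / (1 + (c / ic50_true)^hill)``;
* direct-count readouts (trypan blue, Hoechst nuclei, H2B-mRuby nuclei)
  observe N(c) with counting (Poisson) noise, H2B additionally thinned
  binomially by the transduction fraction of the cell line;
* the metabolic (XTT) readout observes ``N(c) * phi(c)`` — a drug that
  raises per-cell mitochondrial activity (phi > 1) inflates the apparent
  viability even though the same number of cells is present. By default phi
  applies only at concentrations that actually reduce cell number (the toxic
  range), where the bias is observed in practice;
* microscopy fields are disk cells with concentric nuclei in two size
  populations, a mitochondria speckle compartment with per-cell intensity, a
  2-D polynomial illumination background and Gaussian photon noise;
* per-nucleus reporter fluorescence is log-normal with a per-image random
  effect, shifted multiplicatively by a drug's ``reporter_shift`` — which is
  why per-image means, not single nuclei, are the valid test unit.

Setting ``noise_cv = 0`` on the plate config switches all stochastic
readouts to their exact expectations, so closed-form identities hold to the
last digit. All randomness flows from one master seed; each well/field gets
a private substream derived by hashing its labels, so outputs are
reproducible and insensitive to generation order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DrugEffectSpec",
    "PlateConfig",
    "FieldSpec",
    "FieldData",
    "FieldGenerationError",
    "generate_viability_plate",
    "sample_consistency_panel",
    "generate_field",
    "generate_dynamics",
    "generate_reporter_intensities",
    "subseed",
]

BLANK_DRUG = "BLANK"
PLATE_COLUMNS = [
    "method", "cell_line", "drug", "conc_uM", "time_h",
    "replicate", "field", "value", "true_cells", "true_viability",
]


def subseed(master_seed: int, *parts) -> np.random.Generator:
    """Deterministic per-(labels) RNG substream from one master seed."""
    tag = "|".join(str(p) for p in parts).encode()
    h = int.from_bytes(hashlib.blake2b(tag, digest_size=4).digest(), "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), h]))


@dataclass(frozen=True)
class DrugEffectSpec:
    """Ground-truth effect of one drug on one cell population.

    ``metabolic_factor_phi`` multiplies the per-cell XTT signal at toxic
    concentrations; ``size_factor`` scales cell area; ``mito_activity_factor``
    scales per-pixel mitochondria intensity; ``reporter_shift`` scales
    per-nucleus reporter fluorescence; ``growth_rate``/``kill_rate`` are
    per-hour rates for the dynamics model.
    """

    name: str
    ic50_true: float  # µM
    hill: float = 1.0
    emax: float = 1.0  # maximum inhibited fraction; < 1 => cytostatic floor
    metabolic_factor_phi: float = 1.0
    size_factor: float = 1.0
    mito_activity_factor: float = 1.0
    reporter_shift: float = 1.0
    kill_rate: float = 0.0
    growth_rate: float = 0.0

    def __post_init__(self):
        if not (self.ic50_true > 0 and self.hill > 0):
            raise ValueError("ic50_true and hill must be positive")
        if not (0 < self.emax <= 1):
            raise ValueError("emax must be in (0, 1]")
        for v in (self.metabolic_factor_phi, self.size_factor,
                  self.mito_activity_factor, self.reporter_shift):
            if not np.isfinite(v) or v < 0:
                raise ValueError("effect multipliers must be finite and >= 0")

    def occupancy(self, conc) -> np.ndarray:
        """Hill occupancy (c/IC50)^h / (1 + (c/IC50)^h) of the drug effect."""
        c = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            u = (c / self.ic50_true) ** self.hill
        return u / (1.0 + u)

    def viability(self, conc) -> np.ndarray:
        """True surviving fraction N(c)/N0: 1 - emax * occupancy.

        With the default ``emax = 1`` this is the plain constrained logistic
        ``1 / (1 + (c/ic50_true)^hill)``; ``emax < 1`` models cytostatic
        drugs whose cell number floors at ``1 - emax`` of control instead of
        reaching zero.
        """
        return 1.0 - self.emax * self.occupancy(conc)

    def phi(self, conc, toxic_only: bool = True) -> np.ndarray:
        """Per-cell metabolic multiplier.

        By default the bias is occupancy-scaled, ``1 + (phi - 1) * (1 - v(c))``:
        untreated-like cells show no bias, fully drug-engaged cells show the
        full factor, and the apparent-viability distortion
        ``(phi - 1) * (1 - v) * v`` peaks mid-curve — matching the
        observation that metabolic over-reporting is largest at doses that
        only partially reduce proliferation. ``toxic_only=False`` applies the
        constant factor at every nonzero concentration instead.
        """
        c = np.asarray(conc, dtype=float)
        if not toxic_only:
            return np.where(c > 0, self.metabolic_factor_phi, 1.0)
        occ = self.occupancy(c)
        return np.where(c > 0, 1.0 + (self.metabolic_factor_phi - 1.0) * occ, 1.0)


@dataclass(frozen=True)
class PlateConfig:
    """Layout and noise model for a simulated viability plate."""

    methods: tuple = ("XTT", "TB", "Hoechst", "H2B")
    concentrations: tuple = (0.05, 0.15, 0.45, 1.35, 4.05, 12.15, 36.45, 109.35)
    replicates: int = 4
    fields_per_well: int = 6
    cell_lines: tuple = ("H1299",)
    transduction_fraction: dict = field(default_factory=lambda: {"H1299": 0.95})
    cells_per_well: int = 5000
    field_view_fraction: float = 0.02  # fraction of the well one field images
    tb_counted_cells: int = 200  # hemocytometer aliquot size at control density
    noise_cv: float = 0.05  # CV of XTT absorbance noise; 0 => exact expectations
    xtt_blank: float = 0.05  # absorbance of medium + reagent, no cells
    xtt_gain_per_cell: float = 1.0 / 5000.0
    timepoint_h: float = 72.0
    phi_toxic_only: bool = True
    seed: int = 0

    def __post_init__(self):
        if not self.methods:
            raise ValueError("empty method set")
        unknown = set(self.methods) - {"XTT", "TB", "Hoechst", "H2B"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        c = np.asarray(self.concentrations, dtype=float)
        if c.size < 2 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly ascending and > 0")
        for line in self.cell_lines:
            tf = self.transduction_fraction.get(line)
            if tf is None or not (0 <= tf <= 1):
                raise ValueError(f"transduction_fraction for {line} must be in [0, 1]")


def generate_viability_plate(
    cfg: PlateConfig,
    drugs: list[DrugEffectSpec] | dict,
    concentrations_by_drug: dict | None = None,
) -> pd.DataFrame:
    """Long-format readout table with ground-truth columns.

    Rows cover every method x cell line x drug x concentration (including the
    DMSO control at concentration 0) x replicate, with one row per imaging
    field for the two imaging methods. XTT plates additionally carry blank
    rows (``drug == "BLANK"``) for medium + reagent wells.

    ``drugs`` is either one list shared by every cell line or a mapping
    ``cell_line -> list`` when sensitivities differ between lines (the drug
    *names* must then agree across lines). ``concentrations_by_drug`` lets
    each drug use its own ascending dose range, as real screens do;
    otherwise ``cfg.concentrations`` applies to all drugs.
    """
    drugs_by_line = drugs if isinstance(drugs, dict) else {l: drugs for l in cfg.cell_lines}
    if set(drugs_by_line) != set(cfg.cell_lines):
        raise ValueError("drugs dict must cover exactly cfg.cell_lines")
    if any(len(ds) == 0 for ds in drugs_by_line.values()):
        raise ValueError("need at least one drug")
    deterministic = cfg.noise_cv == 0
    n0 = float(cfg.cells_per_well)
    rows = []
    for line in cfg.cell_lines:
        tf = cfg.transduction_fraction[line]
        for drug in drugs_by_line[line]:
            conc_list = (
                concentrations_by_drug.get(drug.name, cfg.concentrations)
                if concentrations_by_drug
                else cfg.concentrations
            )
            c_arr = np.asarray(conc_list, dtype=float)
            if c_arr.size < 4 or np.any(c_arr <= 0) or np.any(np.diff(c_arr) <= 0):
                raise ValueError(
                    f"{drug.name}: concentrations must be >= 4, ascending, positive"
                )
            for conc in (0.0, *conc_list):
                v = float(drug.viability(conc))
                n_true = n0 * v
                phi = float(drug.phi(conc, cfg.phi_toxic_only))
                for method in cfg.methods:
                    for rep in range(1, cfg.replicates + 1):
                        rng = subseed(cfg.seed, line, drug.name, method, conc, rep)
                        if method == "XTT":
                            mean = cfg.xtt_blank + cfg.xtt_gain_per_cell * n_true * phi
                            val = mean if deterministic else mean * (
                                1.0 + cfg.noise_cv * rng.standard_normal()
                            )
                            rows.append((method, line, drug.name, conc,
                                         cfg.timepoint_h, rep, 1, val, n_true, v))
                        elif method == "TB":
                            # manual chamber count of a fixed aliquot, not the well
                            lam = cfg.tb_counted_cells * v
                            val = lam if deterministic else float(rng.poisson(lam))
                            rows.append((method, line, drug.name, conc,
                                         cfg.timepoint_h, rep, 1, val, n_true, v))
                        else:
                            lam = n_true * cfg.field_view_fraction
                            for f in range(1, cfg.fields_per_well + 1):
                                count = lam if deterministic else float(rng.poisson(lam))
                                if method == "H2B":
                                    count = count * tf if deterministic else float(
                                        rng.binomial(int(count), tf)
                                    )
                                rows.append((method, line, drug.name, conc,
                                             cfg.timepoint_h, rep, f, count, n_true, v))
        if "XTT" in cfg.methods:
            for rep in range(1, cfg.replicates + 1):
                rng = subseed(cfg.seed, line, BLANK_DRUG, "XTT", 0.0, rep)
                val = cfg.xtt_blank if deterministic else cfg.xtt_blank * (
                    1.0 + cfg.noise_cv * rng.standard_normal()
                )
                rows.append(("XTT", line, BLANK_DRUG, 0.0, cfg.timepoint_h,
                             rep, 1, val, 0.0, np.nan))
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def sample_consistency_panel(
    seed: int,
    n_drugs: int = 8,
    n_biased: int = 3,
    cell_lines: tuple = ("L1", "L2", "L3", "L4"),
    noise_cv: float = 0.05,
    replicates: int = 2,
):
    """Random 4-method screening panel with planted XTT metabolic bias.

    Emulates a small cell-line screen: each drug gets its own ~2.2-decade,
    8-point dose window roughly centred on its typical potency, and each
    cell line's true IC50 scatters log-normally (SD 0.5 decades) around that
    potency. The first ``n_biased`` drugs are potent cytostatic agents with
    a metabolic boost — incomplete maximal inhibition (emax 0.5-0.75) plus
    per-cell XTT factor phi 1.6-2.5, the palbociclib/dasatinib-like profile
    that makes metabolic readouts plateau above 50% apparent viability; the
    remainder are fully cytotoxic with at most mild bias (phi <= 1.3).

    Returns ``(cfg, drugs_by_line, concentrations_by_drug)`` ready for
    :func:`generate_viability_plate`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    drugs_by_line: dict = {l: [] for l in cell_lines}
    conc_by_drug: dict = {}
    for i in range(n_drugs):
        hill = float(rng.uniform(0.7, 2.0))
        if i < n_biased:
            base = float(10 ** rng.uniform(-1.0, 0.0))
            emax = float(rng.uniform(0.5, 0.75))
            phi = float(rng.uniform(1.6, 2.5))
        else:
            base = float(10 ** rng.uniform(-1.0, 1.0))
            emax = 1.0
            phi = float(rng.uniform(1.0, 1.3))
        name = f"drug{i:02d}"
        center = base * 10 ** rng.uniform(-0.4, 0.4)
        conc_by_drug[name] = tuple(center * np.logspace(-1.1, 1.1, 8))
        for line in cell_lines:
            fac = float(10 ** rng.normal(0.0, 0.5))
            drugs_by_line[line].append(
                DrugEffectSpec(name, ic50_true=base * fac, hill=hill, emax=emax,
                               metabolic_factor_phi=phi)
            )
    cfg = PlateConfig(
        cell_lines=tuple(cell_lines),
        transduction_fraction={l: 0.9 for l in cell_lines},
        noise_cv=noise_cv,
        replicates=replicates,
        seed=int(seed),
    )
    return cfg, drugs_by_line, conc_by_drug


class FieldGenerationError(RuntimeError):
    """Raised when the requested cells cannot be placed without overlap."""


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and optics of one simulated microscopy field."""

    height: int = 512
    width: int = 512
    n_cells: int = 50
    big_fraction: float = 0.0  # fraction of cells drawn from the big population
    nucleus_diameter_small: float = 14.0
    nucleus_diameter_big: float = 40.0
    cell_diameter_small: float = 35.0
    cell_diameter_big: float = 150.0
    mito_fraction: float = 0.15  # of (cell minus nucleus) area
    background_poly_coeffs: tuple = (200.0, 60.0, 40.0, 20.0, 0.0, 10.0)
    photon_noise_sd: float = 30.0
    nucleus_intensity: float = 12000.0
    cell_intensity: float = 6000.0
    mito_intensity: float = 8000.0
    reporter_base_intensity: float = 10000.0
    reporter_sigma: float = 0.2  # log-normal sigma of per-nucleus fluorescence
    allow_overlap: bool = False
    margin_px: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for d in (self.nucleus_diameter_small, self.nucleus_diameter_big,
                  self.cell_diameter_small, self.cell_diameter_big):
            if d <= 0:
                raise ValueError("diameters must be positive")
        if not (0 < self.mito_fraction < 1):
            raise ValueError("mito_fraction must be in (0, 1)")
        if not (0 <= self.big_fraction <= 1):
            raise ValueError("big_fraction must be in [0, 1]")


@dataclass
class FieldData:
    """Rendered channels plus ground truth for one field."""

    channels: dict  # nuclei / tubulin / mito / reporter -> uint16 images
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    mito_mask: np.ndarray
    truth: pd.DataFrame  # per-cell ground truth
    background: np.ndarray  # the noiseless polynomial background


def _poly_background(spec: FieldSpec) -> np.ndarray:
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    y = 2.0 * yy / spec.height - 1.0
    x = 2.0 * xx / spec.width - 1.0
    terms = [np.ones_like(y), x, y, x * x, x * y, y * y]
    coeffs = list(spec.background_poly_coeffs) + [0.0] * (6 - len(spec.background_poly_coeffs))
    bg = np.zeros_like(y)
    for c, t in zip(coeffs[:6], terms):
        bg += c * t
    return bg


def _place_centers(spec: FieldSpec, radii: np.ndarray, rng: np.random.Generator):
    """Jittered-grid placement guaranteeing pairwise non-overlap."""
    n = radii.size
    if spec.allow_overlap:
        ys = rng.uniform(radii, spec.height - radii)
        xs = rng.uniform(radii, spec.width - radii)
        return ys, xs
    pitch = 2.0 * radii.max() + spec.margin_px
    ny = int(spec.height // pitch)
    nx = int(spec.width // pitch)
    if ny * nx < n:
        raise FieldGenerationError(
            f"cannot place {n} non-overlapping cells of radius {radii.max():.0f} "
            f"on a {spec.height}x{spec.width} field"
        )
    sites = [(i, j) for i in range(ny) for j in range(nx)]
    chosen = rng.choice(len(sites), size=n, replace=False)
    ys, xs = [], []
    for idx, r in zip(chosen, radii):
        i, j = sites[idx]
        slack = pitch / 2.0 - r - spec.margin_px / 2.0
        slack = max(slack, 0.0)
        cy = (i + 0.5) * pitch + rng.uniform(-slack, slack)
        cx = (j + 0.5) * pitch + rng.uniform(-slack, slack)
        ys.append(np.clip(cy, r, spec.height - r))
        xs.append(np.clip(cx, r, spec.width - r))
    return np.asarray(ys), np.asarray(xs)


def generate_field(spec: FieldSpec, effect: DrugEffectSpec) -> FieldData:
    """Render one four-channel field with full per-cell ground truth.

    Cells are disks (two size populations, scaled by ``effect.size_factor``)
    with concentric disk nuclei; each cell owns a random speckle set of
    mitochondria pixels at per-pixel intensity
    ``mito_intensity * effect.mito_activity_factor``. The per-cell truth table
    stores areas and the noiseless integrated mitochondria intensity, whose
    sum over cells equals the total signal over true mitochondria pixels by
    construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed]))
    h, w = spec.height, spec.width
    background = _poly_background(spec)
    chan = {k: background.copy() for k in ("nuclei", "tubulin", "mito", "reporter")}
    cell_mask = np.zeros((h, w), dtype=np.int32)
    nucleus_mask = np.zeros((h, w), dtype=np.int32)
    mito_mask = np.zeros((h, w), dtype=np.int32)
    records = []
    n = spec.n_cells
    if n > 0:
        big = rng.random(n) < spec.big_fraction
        cell_d = np.where(big, spec.cell_diameter_big, spec.cell_diameter_small)
        cell_d = cell_d * effect.size_factor
        nuc_d = np.where(big, spec.nucleus_diameter_big, spec.nucleus_diameter_small)
        radii = cell_d / 2.0
        ys, xs = _place_centers(spec, radii, rng)
        mito_per_px = spec.mito_intensity * effect.mito_activity_factor
        for i in range(n):
            lab = i + 1
            r_cell, r_nuc = cell_d[i] / 2.0, nuc_d[i] / 2.0
            # work in a bounding box around the cell, not the whole frame
            y0 = max(int(np.floor(ys[i] - r_cell)) - 1, 0)
            y1 = min(int(np.ceil(ys[i] + r_cell)) + 2, h)
            x0 = max(int(np.floor(xs[i] - r_cell)) - 1, 0)
            x1 = min(int(np.ceil(xs[i] + r_cell)) + 2, w)
            box = np.s_[y0:y1, x0:x1]
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (yy - ys[i]) ** 2 + (xx - xs[i]) ** 2
            cell_px = d2 <= r_cell**2
            nuc_px = d2 <= r_nuc**2
            cell_mask[box][cell_px] = lab
            nucleus_mask[box][nuc_px] = lab
            chan["tubulin"][box][cell_px] += spec.cell_intensity
            chan["nuclei"][box][nuc_px] += spec.nucleus_intensity
            rep_int = spec.reporter_base_intensity * effect.reporter_shift
            if spec.reporter_sigma > 0:
                rep_int *= float(rng.lognormal(0.0, spec.reporter_sigma))
            chan["reporter"][box][nuc_px] += rep_int
            cyto_local = np.flatnonzero(cell_px & ~nuc_px)
            n_mito = int(round(spec.mito_fraction * cyto_local.size))
            sel_local = rng.choice(cyto_local, size=min(n_mito, cyto_local.size), replace=False)
            box_rows = sel_local // (x1 - x0) + y0
            box_cols = sel_local % (x1 - x0) + x0
            sel = box_rows * w + box_cols
            mito_mask.ravel()[sel] = lab
            chan["mito"].ravel()[sel] += mito_per_px
            records.append({
                "cell_id": lab,
                "size_class": "big" if big[i] else "small",
                "cell_area_px": int(cell_px.sum()),
                "nucleus_area_px": int(nuc_px.sum()),
                "mito_area_px": int(sel.size),
                "mito_intensity_per_px": mito_per_px,
                "integrated_mito_intensity": mito_per_px * float(sel.size),
                "reporter_intensity": rep_int,
                "centroid_row": float(ys[i]),
                "centroid_col": float(xs[i]),
            })
    for k in chan:
        img = chan[k]
        if spec.photon_noise_sd > 0:
            img = img + rng.normal(0.0, spec.photon_noise_sd, size=img.shape)
        chan[k] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(
        records,
        columns=["cell_id", "size_class", "cell_area_px", "nucleus_area_px",
                 "mito_area_px", "mito_intensity_per_px",
                 "integrated_mito_intensity", "reporter_intensity",
                 "centroid_row", "centroid_col"],
    )
    return FieldData(chan, cell_mask, nucleus_mask, mito_mask, truth, background)


def generate_dynamics(
    cfg: PlateConfig, effect: DrugEffectSpec, timepoints
) -> pd.DataFrame:
    """Nuclei-count time series per concentration.

    Counts follow ``N(t) = N0 * exp(r(c) * t)`` with net rate
    ``r(c) = growth_rate - kill_rate * occ(c)`` where
    ``occ(c) = (c/IC50)^h / (1 + (c/IC50)^h)`` is the Hill occupancy of the
    drug effect. Poisson counting noise unless ``cfg.noise_cv == 0``.
    """
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise ValueError("timepoints must be non-negative")
    if 0.0 not in t:
        raise ValueError("timepoints must include 0")
    deterministic = cfg.noise_cv == 0
    n0 = cfg.cells_per_well * cfg.field_view_fraction
    rows = []
    for conc in (0.0, *cfg.concentrations):
        occ = float(effect.occupancy(conc))
        rate = effect.growth_rate - effect.kill_rate * occ
        for rep in range(1, cfg.replicates + 1):
            rng = subseed(cfg.seed, "dyn", effect.name, conc, rep)
            for ti in t:
                mean = n0 * np.exp(rate * ti)
                count = mean if deterministic else float(rng.poisson(mean))
                rows.append((effect.name, conc, ti, rep, count, mean))
    return pd.DataFrame(
        rows, columns=["drug", "conc_uM", "time_h", "replicate", "count", "true_count"]
    )


def generate_reporter_intensities(
    cfg: PlateConfig,
    effect: DrugEffectSpec,
    n_images: int,
    nuclei_per_image: int,
    base_intensity: float = 10000.0,
    nucleus_sigma: float = 0.2,
    image_sigma: float = 0.05,
    group: str | None = None,
) -> pd.DataFrame:
    """Per-nucleus reporter intensities grouped by image.

    Intensity = base * reporter_shift * exp(image effect) * log-normal
    nucleus noise. The per-image random effect (sd ``image_sigma`` on the
    natural-log scale) is what makes single nuclei pseudoreplicates and the
    per-image mean the correct analysis unit. ``nucleus_sigma = 0`` and
    ``image_sigma = 0`` give exactly ``base * reporter_shift`` everywhere.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if nuclei_per_image < 1:
        raise ValueError("nuclei_per_image must be >= 1")
    name = group if group is not None else effect.name
    rows = []
    for img in range(1, n_images + 1):
        rng = subseed(cfg.seed, "reporter", name, img)
        img_eff = np.exp(rng.normal(0.0, image_sigma)) if image_sigma > 0 else 1.0
        mu = base_intensity * effect.reporter_shift * img_eff
        if nucleus_sigma > 0:
            vals = mu * rng.lognormal(0.0, nucleus_sigma, size=nuclei_per_image)
        else:
            vals = np.full(nuclei_per_image, mu)
        for lab, v in enumerate(vals, start=1):
            rows.append((name, img, lab, float(v)))
    return pd.DataFrame(
        rows, columns=["drug", "image_id", "nucleus_label", "median_intensity"]
    )
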