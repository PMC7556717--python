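"""Synthetic cytospin imagery and longitudinal cohorts with known ground truth.

No raw patient imagery is publicly available for this assay, so the package
ships a generator that emulates the statistical structure the analysis
relies on:

* low-resolution tile scans of cytospun cell fields containing leukocytes
  (DAPI+/CD45+/CK-), circulating tumor cells (DAPI+/CK+/CD45-/TUB+/AR+) and
  small debris;
* high-resolution 5-channel z-stacks of single cells in which the tubulin
  channel is rendered as a mixture of a diffuse textured component and, as
  ``bundling_level`` rises from 0 to 1, an increasing number of bright
  anisotropic filament ridges — so the expected MT-DTE score is increasing
  in ``bundling_level``;
* whole longitudinal cohorts (patients x timepoints, Poisson cell counts,
  responder vs. stable bundling trajectories) written as TIFFs plus a
  manifest CSV.

Filaments are drawn as Gaussian ridges with random position, orientation
and length of the order of the cell diameter; this is a phenomenological
stand-in for taxane-induced microtubule bundles, sufficient because the
downstream score depends only on the upper tail of the intensity
histogram, not on filament topology.  Intensities are generated in the
16-bit range so the 8-bit export path is exercised.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .exceptions import DesignError, PlacementError, ValidationError
from .image_io import CANONICAL_CHANNELS, MultichannelStack, write_stack
from .timepoints import CONTRAST_PAIRS, TIMEPOINT_LABELS

INT16_MAX = 65535.0


# ---------------------------------------------------------------------------
# phenotypes and noise
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian read noise, optionally followed by Poisson shot noise.

    The default read-noise standard deviation is 2% of the default CTC
    cytokeratin mean.
    """

    gaussian_sd: float = 300.0
    poisson: bool = False

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValidationError("gaussian_sd must be >= 0")


@dataclass(frozen=True)
class CellPhenotype:
    """A renderable cell class: marker intensity profile plus geometry.

    ``bundling_level`` in [0, 1] parameterizes the tubulin channel from
    fully diffuse (0) to maximally bundled (1); it is defined only for
    kinds with a genuine tubulin signal (CTCs).
    """

    kind: str  # "CTC" | "leukocyte" | "debris"
    marker_means: Mapping[str, float]
    marker_cvs: Mapping[str, float]
    diameter_um: float
    bundling_level: float | None = None
    nucleus_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.kind not in ("CTC", "leukocyte", "debris"):
            raise ValidationError(f"unknown phenotype kind {self.kind!r}")
        if self.diameter_um <= 0:
            raise ValidationError("diameter_um must be > 0")
        means = self.marker_means
        if self.kind == "CTC" and not means.get("CK", 0) > means.get("CD45", 0):
            raise ValidationError("CTC phenotype requires CK mean > CD45 mean")
        if self.kind == "leukocyte" and not means.get("CD45", 0) > means.get("CK", 0):
            raise ValidationError("leukocyte phenotype requires CD45 mean > CK mean")
        if self.bundling_level is not None:
            if self.kind != "CTC":
                raise ValidationError(
                    "bundling_level is defined only for tubulin-bearing CTC phenotypes"
                )
            if not 0 <= self.bundling_level <= 1:
                raise ValidationError("bundling_level must lie in [0, 1]")
        for ch, cv in self.marker_cvs.items():
            if cv < 0:
                raise ValidationError(f"marker_cvs[{ch!r}] must be >= 0")


def ctc_phenotype(bundling_level: float = 0.0, **overrides) -> CellPhenotype:
    """Default circulating-tumor-cell phenotype (DAPI+/CK+/CD45-/TUB+/AR+)."""
    kw = dict(
        kind="CTC",
        marker_means={"DAPI": 20000, "CK": 15000, "CD45": 250, "TUB": 9000, "AR": 7000},
        marker_cvs={"DAPI": 0.15, "CK": 0.15, "CD45": 0.3, "TUB": 0.12, "AR": 0.15},
        diameter_um=16.0,
        bundling_level=bundling_level,
        nucleus_fraction=0.75,
    )
    kw.update(overrides)
    return CellPhenotype(**kw)


def leukocyte_phenotype(**overrides) -> CellPhenotype:
    """Default leukocyte phenotype (DAPI+/CD45+/CK-)."""
    kw = dict(
        kind="leukocyte",
        marker_means={"DAPI": 18000, "CK": 250, "CD45": 12000, "TUB": 2500, "AR": 250},
        marker_cvs={"DAPI": 0.15, "CK": 0.3, "CD45": 0.15, "TUB": 0.2, "AR": 0.3},
        diameter_um=10.0,
        bundling_level=None,
        nucleus_fraction=0.8,
    )
    kw.update(overrides)
    return CellPhenotype(**kw)


def debris_phenotype(**overrides) -> CellPhenotype:
    """Small DAPI-dim debris rejected by the size filter."""
    kw = dict(
        kind="debris",
        marker_means={"DAPI": 1500, "CK": 3000, "CD45": 200, "TUB": 600, "AR": 200},
        marker_cvs={"DAPI": 0.3, "CK": 0.4, "CD45": 0.3, "TUB": 0.3, "AR": 0.3},
        diameter_um=4.0,
        bundling_level=None,
        nucleus_fraction=1.0,
    )
    kw.update(overrides)
    return CellPhenotype(**kw)


@dataclass(frozen=True)
class CellGroundTruth:
    """What the generator knows about one rendered cell."""

    cell_id: str
    kind: str
    bundling_level: float | None
    channel_levels: Mapping[str, float]
    diameter_um: float
    centroid_px: tuple[float, float] | None = None  # (y, x); None for single-cell stacks


# ---------------------------------------------------------------------------
# high-resolution single-cell stacks
# ---------------------------------------------------------------------------


def _soft_disk(r_grid: np.ndarray, radius: float, edge: float = 1.5) -> np.ndarray:
    """Disk of given radius with a sigmoid edge of scale ``edge`` pixels."""
    return 1.0 / (1.0 + np.exp((r_grid - radius) / edge))


def _draw_levels(
    phenotype: CellPhenotype, rng: np.random.Generator
) -> dict[str, float]:
    """Per-cell channel intensity levels: mean scaled by a truncated normal."""
    levels = {}
    for ch in CANONICAL_CHANNELS:
        mean = float(phenotype.marker_means.get(ch, 0.0))
        cv = float(phenotype.marker_cvs.get(ch, 0.0))
        factor = max(0.1, 1.0 + cv * rng.standard_normal()) if mean > 0 else 0.0
        levels[ch] = mean * factor
    return levels


def _tubulin_texture(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth diffuse texture in [0.15, 1], max-normalized.

    The texture is a low-pass-filtered uniform field raised to the third
    power, so only a small fraction of the cell sits near the texture
    maximum and a purely diffuse cell has a small super-threshold ROI.
    """
    t = gaussian_filter(rng.random(shape), sigma=3.0)
    t -= t.min()
    peak = t.max()
    if peak > 0:
        t /= peak
    return 0.15 + 0.85 * t**3


def render_cell_stack(
    phenotype: CellPhenotype,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    n_z: int = 20,
    field_px: int = 72,
    pixel_size_um: float = 0.3,
    z_step_um: float = 0.24,
) -> tuple[MultichannelStack, CellGroundTruth]:
    """Render one centered cell as a 5-channel high-resolution z-stack.

    The tubulin channel is a diffuse textured component plus
    ``ceil(8 * bundling_level)`` Gaussian filament ridges whose amplitude
    and width grow with ``bundling_level``; the expected MT-DTE score is
    therefore increasing in ``bundling_level``.  All draws come from a
    single seeded generator, so identical inputs give identical stacks.
    """
    if noise is None:
        noise = NoiseModel()
    if not 20 <= n_z <= 40:
        raise ValidationError("n_z must lie in the acquisition range 20-40")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    shape2d = (field_px, field_px)
    yy, xx = np.mgrid[0:field_px, 0:field_px].astype(np.float64)
    cy = cx = (field_px - 1) / 2.0
    r_grid = np.hypot(yy - cy, xx - cx)
    r_cell = phenotype.diameter_um / 2.0 / pixel_size_um
    r_nuc = phenotype.nucleus_fraction * r_cell

    cell_soft = _soft_disk(r_grid, r_cell)
    nuc_soft = _soft_disk(r_grid, r_nuc)

    z = np.arange(n_z, dtype=np.float64)
    gz = np.exp(-((z - (n_z - 1) / 2.0) ** 2) / (2.0 * (n_z / 4.0) ** 2))

    levels = _draw_levels(phenotype, rng)
    stack = np.zeros((len(CANONICAL_CHANNELS), n_z) + shape2d, dtype=np.float64)

    for ci, ch in enumerate(CANONICAL_CHANNELS):
        if levels[ch] <= 0:
            continue
        base2d = nuc_soft if ch == "DAPI" else cell_soft
        if ch == "TUB":
            base2d = base2d * _tubulin_texture(shape2d, rng)
        stack[ci] = levels[ch] * base2d[None, :, :] * gz[:, None, None]

    b = phenotype.bundling_level or 0.0
    if b > 0:
        # Filaments are composited with a per-voxel maximum (against each
        # other and against the diffuse component) so crossings do not
        # create doubled-intensity hot spots that would dominate the
        # dynamic threshold.
        tub_i = CANONICAL_CHANNELS.index("TUB")
        fil = np.zeros((n_z,) + shape2d, dtype=np.float64)
        n_fil = int(np.ceil(8 * b))
        for _ in range(n_fil):
            fy, fx = cy + rng.uniform(-0.4, 0.4) * r_cell, cx + rng.uniform(-0.4, 0.4) * r_cell
            theta = rng.uniform(0, np.pi)
            half_len = rng.uniform(0.7, 1.0) * r_cell
            sigma_w = rng.uniform(0.8, 1.2) + 0.8 * b
            amp = levels["TUB"] * (1.2 + 2.8 * b) * rng.normal(1.0, 0.05)
            d_par = (xx - fx) * np.cos(theta) + (yy - fy) * np.sin(theta)
            d_perp = -(xx - fx) * np.sin(theta) + (yy - fy) * np.cos(theta)
            overhang = np.maximum(np.abs(d_par) - half_len, 0.0)
            ridge = np.exp(
                -(d_perp**2) / (2 * sigma_w**2)
                - (overhang**2) / (2 * (2 * sigma_w) ** 2)
            ) * cell_soft
            zf = rng.uniform(0.3, 0.7) * (n_z - 1)
            gzf = np.exp(-((z - zf) ** 2) / (2 * 2.5**2))
            np.maximum(fil, amp * ridge[None, :, :] * gzf[:, None, None], out=fil)
        np.maximum(stack[tub_i], fil, out=stack[tub_i])

    if noise.gaussian_sd > 0:
        stack += rng.normal(0.0, noise.gaussian_sd, size=stack.shape)
    if noise.poisson:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(np.float64)
    np.clip(stack, 0.0, INT16_MAX, out=stack)

    mc = MultichannelStack(
        pixels=stack.astype(np.float32),
        channel_names=CANONICAL_CHANNELS,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        bit_depth=16,
    )
    truth = CellGroundTruth(
        cell_id="",
        kind=phenotype.kind,
        bundling_level=phenotype.bundling_level,
        channel_levels=levels,
        diameter_um=phenotype.diameter_um,
    )
    return mc, truth


# ---------------------------------------------------------------------------
# low-resolution tile scans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneSpec:
    """Specification of one low-resolution tile-scan field.

    ``cells`` is a sequence of ``(phenotype, count)`` pairs.  Cells are
    placed by rejection sampling with centre separation of at least
    ``(r_i + r_j) * (1 - max_overlap_frac)``.
    """

    cells: tuple[tuple[CellPhenotype, int], ...] = ()
    field_size_px: tuple[int, int] = (768, 768)
    background_mean: float = 100.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    pixel_size_um: float = 1.0
    max_overlap_frac: float = 0.05

    def __post_init__(self) -> None:
        for pheno, count in self.cells:
            if count < 0:
                raise ValidationError(f"negative cell count for {pheno.kind}")
        if self.background_mean < 0:
            raise ValidationError("background_mean must be >= 0")
        if not 0 <= self.max_overlap_frac < 1:
            raise ValidationError("max_overlap_frac must lie in [0, 1)")


def _place_cells(
    spec: SceneSpec, radii: Sequence[float], rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping centres; raise PlacementError if stuck."""
    h, w = spec.field_size_px
    centres: list[tuple[float, float]] = []
    max_tries = 2000 * max(len(radii), 1)
    tries = 0
    for i, r in enumerate(radii):
        margin = r + 2
        while True:
            tries += 1
            if tries > max_tries:
                raise PlacementError(
                    f"could not place {len(radii)} cells in a {h}x{w} field "
                    f"at overlap fraction {spec.max_overlap_frac}"
                )
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            ok = all(
                np.hypot(y - yj, x - xj) >= (r + rj) * (1 - spec.max_overlap_frac)
                for (yj, xj), rj in zip(centres, radii[:i])
            )
            if ok:
                centres.append((y, x))
                break
    return centres


def render_tile_scan(
    spec: SceneSpec,
) -> tuple[MultichannelStack, list[CellGroundTruth]]:
    """Render a single-plane 5-channel field with ground-truth records.

    Returns the tile (z = 1) and one :class:`CellGroundTruth` per rendered
    cell, with its true centroid and phenotype label.  Identical specs
    (including seed) produce identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px

    phenos: list[CellPhenotype] = []
    for pheno, count in spec.cells:
        phenos.extend([pheno] * count)
    radii = [p.diameter_um / 2.0 / spec.pixel_size_um for p in phenos]
    # place big cells first so dense fields still pack
    order = sorted(range(len(phenos)), key=lambda i: -radii[i])
    centres_sorted = _place_cells(
        spec, [radii[i] for i in order], rng
    )
    centres: list[tuple[float, float]] = [(0.0, 0.0)] * len(phenos)
    for slot, i in enumerate(order):
        centres[i] = centres_sorted[slot]

    field_img = np.full((len(CANONICAL_CHANNELS), h, w), spec.background_mean, dtype=np.float64)
    truths: list[CellGroundTruth] = []

    for i, (pheno, (cy, cx)) in enumerate(zip(phenos, centres)):
        r_px = radii[i]
        levels = _draw_levels(pheno, rng)
        win = int(np.ceil(r_px * 1.8)) + 3
        y0, y1 = max(0, int(cy) - win), min(h, int(cy) + win + 1)
        x0, x1 = max(0, int(cx) - win), min(w, int(cx) + win + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        r_grid = np.hypot(yy - cy, xx - cx)
        cell_soft = _soft_disk(r_grid, r_px, edge=0.8)
        nuc_soft = _soft_disk(r_grid, pheno.nucleus_fraction * r_px, edge=0.8)
        for ci, ch in enumerate(CANONICAL_CHANNELS):
            if levels[ch] <= 0:
                continue
            base = nuc_soft if ch == "DAPI" else cell_soft
            field_img[ci, y0:y1, x0:x1] += levels[ch] * base
        truths.append(
            CellGroundTruth(
                cell_id=f"cell_{i:04d}",
                kind=pheno.kind,
                bundling_level=pheno.bundling_level,
                channel_levels=levels,
                diameter_um=pheno.diameter_um,
                centroid_px=(cy, cx),
            )
        )

    if spec.noise.gaussian_sd > 0:
        field_img += rng.normal(0.0, spec.noise.gaussian_sd, size=field_img.shape)
    if spec.noise.poisson:
        field_img = rng.poisson(np.clip(field_img, 0, None)).astype(np.float64)
    np.clip(field_img, 0.0, INT16_MAX, out=field_img)

    tile = MultichannelStack(
        pixels=field_img[:, None, :, :].astype(np.float32),
        channel_names=CANONICAL_CHANNELS,
        pixel_size_um=spec.pixel_size_um,
        z_step_um=1.0,
        bit_depth=16,
    )
    return tile, truths


# ---------------------------------------------------------------------------
# longitudinal cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimepointDesign:
    """Design of one patient x timepoint: expected CTC yield and bundling."""

    expected_ctc: float
    bundling_mean: float
    bundling_sd: float
    status: str = "analyzed"  # or "sample_not_received"

    def __post_init__(self) -> None:
        if self.expected_ctc < 0 or self.bundling_sd < 0:
            raise DesignError("expected_ctc and bundling_sd must be >= 0")
        if not 0 <= self.bundling_mean <= 1:
            raise DesignError("bundling_mean must lie in [0, 1]")
        if self.status not in ("analyzed", "sample_not_received"):
            raise DesignError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class PatientDesign:
    """One synthetic patient: ordered timepoints plus a response profile.

    Responder profiles must have week-1 (C1D8, C2D8) mean bundling strictly
    above the corresponding cycle baseline (C1D1, C2D1); stable profiles
    must not.
    """

    patient_id: str
    response_profile: str  # "responder" | "stable"
    timepoints: tuple[tuple[str, TimepointDesign], ...]

    def __post_init__(self) -> None:
        if self.response_profile not in ("responder", "stable"):
            raise DesignError(f"unknown response profile {self.response_profile!r}")
        labels = [lbl for lbl, _ in self.timepoints]
        dupes = {lbl for lbl in labels if labels.count(lbl) > 1}
        if dupes:
            raise DesignError(f"duplicate timepoint labels for {self.patient_id}: {dupes}")
        unknown = set(labels) - set(TIMEPOINT_LABELS)
        if unknown:
            raise DesignError(
                f"unknown timepoint labels {sorted(unknown)}; allowed: {TIMEPOINT_LABELS}"
            )
        tp = dict(self.timepoints)
        for cycle, (base, week1) in CONTRAST_PAIRS.items():
            if base in tp and week1 in tp:
                delta = tp[week1].bundling_mean - tp[base].bundling_mean
                if self.response_profile == "responder" and not delta > 0:
                    raise DesignError(
                        f"responder {self.patient_id}: cycle-{cycle} week-1 bundling "
                        "mean must exceed the cycle baseline"
                    )
                if self.response_profile == "stable" and delta > 0:
                    raise DesignError(
                        f"stable {self.patient_id}: cycle-{cycle} week-1 bundling mean "
                        "must not exceed the cycle baseline"
                    )

    @property
    def timepoint_map(self) -> dict[str, TimepointDesign]:
        return dict(self.timepoints)


@dataclass(frozen=True)
class CohortDesign:
    """A full synthetic cohort: patients, count model and master seed."""

    patients: tuple[PatientDesign, ...]
    seed: int = 0
    count_model: str = "poisson"  # or "fixed"
    n_background_leukocytes: int = 30

    def __post_init__(self) -> None:
        if self.count_model not in ("poisson", "fixed"):
            raise DesignError(f"unknown count_model {self.count_model!r}")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise DesignError(f"duplicate patient ids: {ids}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "CohortDesign":
        """Load a design from a YAML file mirroring this dataclass."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        patients = []
        for p in raw["patients"]:
            tps = tuple(
                (
                    t["label"],
                    TimepointDesign(
                        expected_ctc=float(t["expected_ctc"]),
                        bundling_mean=float(t["bundling_mean"]),
                        bundling_sd=float(t["bundling_sd"]),
                        status=t.get("status", "analyzed"),
                    ),
                )
                for t in p["timepoints"]
            )
            patients.append(
                PatientDesign(
                    patient_id=str(p["patient_id"]),
                    response_profile=str(p["response_profile"]),
                    timepoints=tps,
                )
            )
        return cls(
            patients=tuple(patients),
            seed=int(raw.get("seed", 0)),
            count_model=str(raw.get("count_model", "poisson")),
            n_background_leukocytes=int(raw.get("n_background_leukocytes", 30)),
        )

    def to_yaml(self, path: str | os.PathLike) -> None:
        doc = {
            "seed": self.seed,
            "count_model": self.count_model,
            "n_background_leukocytes": self.n_background_leukocytes,
            "patients": [
                {
                    "patient_id": p.patient_id,
                    "response_profile": p.response_profile,
                    "timepoints": [
                        {
                            "label": lbl,
                            "expected_ctc": tp.expected_ctc,
                            "bundling_mean": tp.bundling_mean,
                            "bundling_sd": tp.bundling_sd,
                            "status": tp.status,
                        }
                        for lbl, tp in p.timepoints
                    ],
                }
                for p in self.patients
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# Default bundling trajectory values.  Baseline bundling ~0.15 emulates
# largely diffuse pre-treatment microtubule networks; the responder's
# week-1 mean of 0.25 shifts the per-cell score by roughly 1.2 baseline
# cell-level standard deviations (see docs/methods.md for the calibration).
BASELINE_BUNDLING = 0.15
RESPONDER_WEEK1_BUNDLING = 0.25
EARLY_TIMEPOINT_BUNDLING = 0.50
BUNDLING_SD = 0.08


def responder_patient(
    patient_id: str = "P1",
    expected_ctc: float = 10,
    labels: Sequence[str] = ("C1D1", "C1D8", "C2D1", "C2D8"),
) -> PatientDesign:
    """Responder design: week-1 bundling elevated over each cycle baseline."""
    return _profile_patient(patient_id, "responder", expected_ctc, labels)


def stable_patient(
    patient_id: str = "P2",
    expected_ctc: float = 10,
    labels: Sequence[str] = ("C1D1", "C1D8", "C2D1", "C2D8"),
) -> PatientDesign:
    """Stable-disease design: week-1 bundling equal to each cycle baseline."""
    return _profile_patient(patient_id, "stable", expected_ctc, labels)


def _profile_patient(
    patient_id: str, profile: str, expected_ctc: float, labels: Sequence[str]
) -> PatientDesign:
    tps = []
    for lbl in labels:
        if lbl in ("C1D1+4h", "C1D2", "C2D1+4h"):
            # early draws show strong engagement in every profile
            mean = EARLY_TIMEPOINT_BUNDLING
        elif lbl in ("C1D8", "C2D8") and profile == "responder":
            mean = RESPONDER_WEEK1_BUNDLING
        else:
            mean = BASELINE_BUNDLING
        tps.append(
            (lbl, TimepointDesign(expected_ctc=expected_ctc, bundling_mean=mean,
                                  bundling_sd=BUNDLING_SD))
        )
    return PatientDesign(patient_id=patient_id, response_profile=profile,
                         timepoints=tuple(tps))


def default_cohort_design(seed: int = 0) -> CohortDesign:
    """A three-patient cohort (one responder, two stable) over all 7 timepoints."""
    return CohortDesign(
        patients=(
            responder_patient("P1", expected_ctc=8, labels=TIMEPOINT_LABELS),
            stable_patient("P2", expected_ctc=10, labels=TIMEPOINT_LABELS),
            stable_patient("P3", expected_ctc=10, labels=TIMEPOINT_LABELS),
        ),
        seed=seed,
    )


def recovery_design(seed: int = 0, n_cells: int = 10) -> CohortDesign:
    """Responder + stable pair with a fixed number of cells per timepoint.

    Used by the responder-recovery benchmark: baseline-vs-week-1 contrast
    timepoints only, ``n_cells`` CTCs each, responder effect calibrated to
    roughly one cell-level score standard deviation.
    """
    return CohortDesign(
        patients=(
            responder_patient("R1", expected_ctc=n_cells),
            stable_patient("S1", expected_ctc=n_cells),
        ),
        seed=seed,
        count_model="fixed",
    )


def iter_cohort_cells(
    design: CohortDesign,
) -> Iterator[dict]:
    """Yield one record per designed patient x timepoint x cell.

    Records for timepoints with status ``sample_not_received`` or a drawn
    count of 0 carry ``stack=None`` so the timepoint still appears
    downstream.  Each record has keys ``patient_id, timepoint, status,
    cell_id, bundling_level, stack, truth``.
    """
    for p_idx, patient in enumerate(design.patients):
        for t_idx, (label, tp) in enumerate(patient.timepoints):
            ss = np.random.SeedSequence(
                entropy=design.seed, spawn_key=(p_idx, t_idx)
            )
            rng = np.random.default_rng(ss)
            if tp.status != "analyzed":
                yield dict(patient_id=patient.patient_id, timepoint=label,
                           status=tp.status, cell_id=None, bundling_level=None,
                           stack=None, truth=None)
                continue
            if design.count_model == "poisson":
                n = int(rng.poisson(tp.expected_ctc))
            else:
                n = int(round(tp.expected_ctc))
            if n == 0:
                yield dict(patient_id=patient.patient_id, timepoint=label,
                           status="analyzed", cell_id=None, bundling_level=None,
                           stack=None, truth=None)
                continue
            for c in range(n):
                b = float(np.clip(rng.normal(tp.bundling_mean, tp.bundling_sd), 0.0, 1.0))
                pheno = ctc_phenotype(bundling_level=b)
                stack, truth = render_cell_stack(pheno, seed=rng)
                cell_id = f"{patient.patient_id}_{label}_cell{c:03d}"
                truth = replace(truth, cell_id=cell_id)
                yield dict(patient_id=patient.patient_id, timepoint=label,
                           status="analyzed", cell_id=cell_id, bundling_level=b,
                           stack=stack, truth=truth)


MANIFEST_COLUMNS = (
    "patient_id",
    "timepoint",
    "status",
    "file",
    "cell_id",
    "true_label",
    "true_bundling_level",
)


def generate_cohort(
    design: CohortDesign,
    output_dir: str | os.PathLike,
    write_tiles: bool = True,
) -> pd.DataFrame:
    """Materialize a designed cohort on disk and return its manifest.

    Per analyzed patient x timepoint this writes one low-resolution tile
    scan (the designed CTCs plus background leukocytes) and one
    high-resolution z-stack per CTC, then a ``manifest.csv`` listing every
    file with its ground-truth label and bundling level.  Timepoints with
    zero cells or status ``sample_not_received`` still get a manifest row.
    Identical (design, seed) yield byte-identical manifests.
    """
    output_dir = os.fspath(output_dir)
    os.makedirs(output_dir, exist_ok=True)
    rows: list[dict] = []
    by_tp: dict[tuple[str, str], list[dict]] = {}

    for rec in iter_cohort_cells(design):
        key = (rec["patient_id"], rec["timepoint"])
        by_tp.setdefault(key, [])
        if rec["stack"] is None:
            rows.append(dict(patient_id=rec["patient_id"], timepoint=rec["timepoint"],
                             status=rec["status"], file="", cell_id="",
                             true_label="", true_bundling_level=np.nan))
            continue
        by_tp[key].append(rec)
        rel = os.path.join(rec["patient_id"], rec["timepoint"].replace("+", "p"),
                           f"{rec['cell_id']}.tif")
        full = os.path.join(output_dir, rel)
        os.makedirs(os.path.dirname(full), exist_ok=True)
        write_stack(rec["stack"], full)
        rows.append(dict(patient_id=rec["patient_id"], timepoint=rec["timepoint"],
                         status="analyzed", file=rel, cell_id=rec["cell_id"],
                         true_label="CTC",
                         true_bundling_level=rec["bundling_level"]))

    if write_tiles:
        index = {
            (p.patient_id, lbl): (pi, ti)
            for pi, p in enumerate(design.patients)
            for ti, (lbl, _) in enumerate(p.timepoints)
        }
        for (pid, label), recs in sorted(by_tp.items()):
            if not recs:
                continue
            n_ctc = len(recs)
            p_idx, t_idx = index[(pid, label)]
            tile_seed = int(
                np.random.SeedSequence(
                    entropy=design.seed, spawn_key=(1000 + p_idx, t_idx)
                ).generate_state(1)[0] % (2**31)
            )
            spec = SceneSpec(
                cells=(
                    (ctc_phenotype(), n_ctc),
                    (leukocyte_phenotype(), design.n_background_leukocytes),
                ),
                field_size_px=(512, 512),
                seed=tile_seed,
            )
            tile, _ = render_tile_scan(spec)
            rel = os.path.join(pid, label.replace("+", "p"), "tile.tif")
            write_stack(tile, os.path.join(output_dir, rel))
            rows.append(dict(patient_id=pid, timepoint=label, status="analyzed",
                             file=rel, cell_id="", true_label="tile_scan",
                             true_bundling_level=np.nan))

    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest = manifest.sort_values(["patient_id", "timepoint", "true_label", "cell_id"],
                                    kind="mergesort").reset_index(drop=True)
    manifest.to_csv(os.path.join(output_dir, "manifest.csv"), index=False,
                    float_format="%.6f")
    return manifest


__all__ = [
    "NoiseModel",
    "CellPhenotype",
    "ctc_phenotype",
    "leukocyte_phenotype",
    "debris_phenotype",
    "CellGroundTruth",
    "SceneSpec",
    "render_cell_stack",
    "render_tile_scan",
    "TimepointDesign",
    "PatientDesign",
    "CohortDesign",
    "responder_patient",
    "stable_patient",
    "default_cohort_design",
    "recovery_design",
    "iter_cohort_cells",
    "generate_cohort",
    "MANIFEST_COLUMNS",
]
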