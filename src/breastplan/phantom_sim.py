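"""Synthetic thorax phantoms and analytic paired 3D-CRT / IMRT dose engines.

This module emulates two institutional whole-breast radiotherapy cohorts:
``inst1`` (3.75 mm slices, 3D-CRT only) and ``inst2`` (3 mm slices, mixed
3D-CRT/IMRT).  Each phantom is a pseudo-3D stack of axial slices holding a
CT-like intensity volume, binary structure masks (body, lungs, heart,
breast PTV, optional nodal PTV) and per-case anatomical-complexity
covariates (heart-to-chest-wall proximity, chest curvature, PTV size,
node positivity).

Dose is not computed by radiation transport.  Two analytic geometric
engines produce paired plans per phantom:

* ``simulate_dose_3dcrt`` — two opposed tangential beams are modelled as a
  slab ("corridor") through the breast PTV tangent to the chest wall, with
  a Gaussian lateral penumbra and a small in-field ripple standing in for
  wedge inhomogeneity.
* ``simulate_dose_imrt`` — a conformal high-dose component that falls off
  with Euclidean distance from the PTV surface (never exceeding the
  tangential corridor dose outside the PTV, since the PTV lies inside the
  corridor slab) plus a stylised low-dose bath over soft tissue emulating
  the larger irradiated low-dose volume of multi-beam IMRT; the bath is
  strongly attenuated inside the heart and partially inside lung, the way
  an inverse optimiser steers fluence away from organs at risk.

Ground-truth technique labels apply the clinical organ-at-risk constraints
to the *simulated* (not predicted) 3D-CRT dose, standing in for a blinded
observer choosing the simplest adequate technique.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import ndimage

__all__ = [
    "PatientCase",
    "DoseMap",
    "CohortSpec",
    "CohortEntry",
    "DEFAULT_ENGINE_PARAMS",
    "generate_case",
    "build_case",
    "simulate_dose_3dcrt",
    "simulate_dose_imrt",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

PRESCRIPTION_GY = 50.0  # 2 Gy x 25 fractions
MASK_NAMES = ("body", "lung_ipsi", "lung_contra", "heart", "ptv_breast", "ptv_nodes")

#: analytic engine parameters (mm / Gy); shared defaults for both engines
DEFAULT_ENGINE_PARAMS = {
    "penumbra_sigma_mm": 6.0,      # lateral Gaussian falloff of beam edges
    "corridor_margin_mm": 6.0,     # corridor half-width margin beyond the PTV
    "crt_ripple": 0.03,            # in-field inhomogeneity of the tangential plan
    "imrt_bath_gy": 5.3,           # soft-tissue low-dose bath of the IMRT plan
    "imrt_bath_lung_factor": 0.35,
    "imrt_bath_heart_factor": 0.04,
}


class ValidationError(ValueError):
    """A phantom, dose map or configuration violates its contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PatientCase:
    """One synthetic patient: CT-like volume, structure masks and metadata.

    Arrays are indexed ``[z, y, x]`` (axial slice, anterior->posterior row,
    patient-right->patient-left column); ``voxel_spacing`` is ``(dx, dy, dz)``
    in mm.
    """

    case_id: str
    ct: np.ndarray
    voxel_spacing: tuple[float, float, float]
    masks: dict[str, np.ndarray]
    laterality: str
    prescription_dose: float = PRESCRIPTION_GY
    institution: str = "inst1"
    covariates: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.ct.shape

    @property
    def voxel_volume_cm3(self):
        dx, dy, dz = self.voxel_spacing
        return dx * dy * dz / 1000.0

    def validate(self):
        if self.laterality not in ("left", "right"):
            raise ValidationError(f"laterality must be left/right, got {self.laterality}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValidationError("voxel_spacing components must be > 0")
        if self.prescription_dose <= 0:
            raise ValidationError("prescription_dose must be > 0")
        body = self.masks.get("body")
        if body is None:
            raise ValidationError("body mask is required")
        for name, m in self.masks.items():
            if m.shape != self.ct.shape:
                raise ValidationError(f"mask {name!r} shape {m.shape} != ct {self.ct.shape}")
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValidationError(f"mask {name!r} is not binary")
        for name in ("ptv_breast", "heart", "lung_ipsi", "lung_contra"):
            m = self.masks.get(name)
            if m is not None and np.any(m & ~body):
                raise ValidationError(f"{name} extends outside body")
        ptv = self.masks.get("ptv_breast")
        lung = self.masks.get("lung_ipsi")
        if ptv is not None and lung is not None and ptv.sum() > 0:
            overlap = np.sum(ptv & lung) / ptv.sum()
            if overlap >= 0.05:
                raise ValidationError(f"PTV/lung overlap fraction {overlap:.3f} >= 0.05")
        return self


@dataclass
class DoseMap:
    """Absolute dose in Gy on the owning case's grid."""

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    technique: str
    case_id: str

    def validate(self, case: PatientCase | None = None):
        if self.technique not in ("3DCRT", "IMRT"):
            raise ValidationError(f"unknown technique {self.technique!r}")
        if np.any(self.values < 0):
            raise ValidationError("negative dose values")
        if case is not None:
            if self.values.shape != case.ct.shape:
                raise ValidationError("dose grid does not match case grid")
            if self.values.max() > 1.3 * case.prescription_dose:
                raise ValidationError("dose exceeds 1.3 x prescription")
        return self


@dataclass
class CohortSpec:
    """Sampling distribution of a synthetic institutional cohort.

    Complexity covariates per case:

    * ``heart_proximity`` ~ Beta(a, b) in [0, 1]: 0 = heart deep in the
      mediastinum, 1 = heart abutting the chest wall under the tangents.
    * ``curvature`` ~ U(lo, hi): how far the PTV wraps around the chest,
      which deepens the tangential corridor.
    * ``ptv_size`` ~ U(lo, hi): angular extent / thickness of the breast PTV.
    * node-positive cases additionally carry a nodal PTV.
    """

    n_cases: int
    institution: str = "inst1"
    seed: int = 0
    heart_proximity_beta: tuple[float, float] = (1.8, 2.2)
    curvature_range: tuple[float, float] = (0.0, 1.0)
    ptv_size_range: tuple[float, float] = (0.0, 1.0)
    node_positive_prob: float = 0.75
    left_prob: float = 0.5
    grid_size: tuple[int, int, int] = (12, 96, 96)  # (nz, ny, nx)

    def validate(self):
        if self.n_cases < 1:
            raise ValidationError("n_cases must be >= 1")
        if self.institution not in ("inst1", "inst2"):
            raise ValidationError(f"institution must be inst1/inst2, got {self.institution!r}")
        if not (0.0 <= self.node_positive_prob <= 1.0):
            raise ValidationError("node_positive_prob must be in [0, 1]")
        if not (0.0 <= self.left_prob <= 1.0):
            raise ValidationError("left_prob must be in [0, 1]")
        if any(p <= 0 for p in self.heart_proximity_beta):
            raise ValidationError("heart_proximity_beta parameters must be > 0")
        for name in ("curvature_range", "ptv_size_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValidationError(f"{name} must satisfy 0 <= lo <= hi <= 1")
        if any(s < 8 for s in self.grid_size):
            raise ValidationError("grid_size components must be >= 8")
        return self

    @property
    def slice_thickness_mm(self):
        # Inst1 scanner used 3.75 mm slices, Inst2 3 mm.
        return 3.75 if self.institution == "inst1" else 3.0

    @classmethod
    def for_institution(cls, institution, n_cases, seed=0, **overrides):
        """Defaults emulating the two cohorts' case mixes.

        inst1 treats every anatomy with 3D-CRT (no selection bias) and has a
        higher nodal-involvement fraction; inst2 has a slightly broader
        complexity mix and fewer node-positive cases.
        """
        base = dict(
            inst1=dict(heart_proximity_beta=(1.8, 2.4), node_positive_prob=0.75),
            inst2=dict(heart_proximity_beta=(1.3, 3.0), node_positive_prob=0.36),
        )[institution]
        base.update(overrides)
        return cls(n_cases=n_cases, institution=institution, seed=seed, **base).validate()


class CohortEntry(NamedTuple):
    case: PatientCase
    dose_3dcrt: DoseMap
    dose_imrt: DoseMap
    label: str  # ground-truth technique: "3DCRT" or "IMRT"


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def _ellipse(yy, xx, cy, cx, ry, rx):
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_case(spec: CohortSpec, index: int) -> PatientCase:
    """Deterministically generate phantom ``index`` of the cohort ``spec``.

    Complexity covariates are sampled from the cohort's distributions and
    recorded on the case, so ground-truth difficulty is always known.
    """
    spec.validate()
    if not (0 <= index < spec.n_cases):
        raise ValidationError(f"index {index} out of range for n_cases={spec.n_cases}")
    rng = np.random.default_rng([max(spec.seed, 0) + 1, index])
    a, b = spec.heart_proximity_beta
    return build_case(
        case_id=f"{spec.institution}-{spec.seed:05d}-{index:04d}",
        grid_size=spec.grid_size,
        slice_thickness_mm=spec.slice_thickness_mm,
        institution=spec.institution,
        heart_proximity=float(rng.beta(a, b)),
        curvature=float(rng.uniform(*spec.curvature_range)),
        ptv_size=float(rng.uniform(*spec.ptv_size_range)),
        node_positive=bool(rng.random() < spec.node_positive_prob),
        laterality="left" if rng.random() < spec.left_prob else "right",
        body_jitter=(float(rng.random()), float(rng.random())),
        noise_seed=int(rng.integers(2 ** 31)),
    )


def build_case(case_id, grid_size=(12, 96, 96), slice_thickness_mm=3.0,
               institution="inst2", heart_proximity=0.3, curvature=0.5,
               ptv_size=0.5, node_positive=False, laterality="left",
               body_jitter=(0.5, 0.5), noise_seed=0) -> PatientCase:
    """Construct a phantom from explicit complexity covariates.

    ``heart_proximity``, ``curvature`` and ``ptv_size`` live in [0, 1];
    ``body_jitter`` perturbs the body outline so two cases with identical
    covariates need not be congruent.
    """
    for name, v in (("heart_proximity", heart_proximity), ("curvature", curvature),
                    ("ptv_size", ptv_size)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    proximity = heart_proximity
    nz, ny, nx = grid_size
    sgn = 1.0 if laterality == "left" else -1.0  # patient left = +x

    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    cy, cx = 0.54 * ny, 0.5 * nx
    body_ry = ny * (0.27 + 0.02 * body_jitter[0])
    body_rx = nx * (0.40 + 0.03 * body_jitter[1])

    masks = {name: np.zeros((nz, ny, nx), dtype=np.uint8) for name in MASK_NAMES}
    ct = np.full((nz, ny, nx), -1000.0, dtype=np.float32)
    zc = (nz - 1) / 2.0

    # heart centre interpolates between a deep mediastinal position and the
    # left anterior chest wall as proximity -> 1
    heart_rx, heart_ry = 0.095 * nx, 0.085 * ny
    h_cx = cx + 0.04 * nx + proximity * 0.05 * nx  # heart is anatomically left
    h_cy_deep = cy + 0.05 * ny
    h_cy_wall = cy - body_ry + heart_ry + 5.0
    h_cy = h_cy_deep + proximity * (h_cy_wall - h_cy_deep)

    for z in range(nz):
        env = 1.0 - 0.18 * ((z - zc) / max(zc, 1.0)) ** 2  # slow axial variation
        ry, rx = body_ry * (0.94 + 0.06 * env), body_rx * (0.94 + 0.06 * env)
        body = _ellipse(yy, xx, cy, cx, ry, rx)

        lung_ry, lung_rx = 0.165 * ny * env ** 0.5, 0.105 * nx * env ** 0.5
        l_cy = cy + 0.085 * ny
        lung_left = _ellipse(yy, xx, l_cy, cx + 0.155 * nx, lung_ry, lung_rx) & body
        lung_right = _ellipse(yy, xx, l_cy, cx - 0.155 * nx, lung_ry, lung_rx) & body

        heart = _ellipse(yy, xx, h_cy, h_cx, heart_ry * env ** 0.3, heart_rx * env ** 0.3) & body
        lung_left &= ~heart
        lung_right &= ~heart

        # breast PTV: polar crescent on the anterior-lateral surface
        ang = np.arctan2(sgn * (xx - cx), -(yy - cy))  # 0 = anterior, + toward PTV side
        phi_c = np.deg2rad(40.0 + 8.0 * curvature)
        half_w = np.deg2rad((24.0 + 12.0 * ptv_size + 6.0 * curvature) * (0.75 + 0.25 * env))
        r = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)  # elliptical radius
        thickness = 0.14 + 0.06 * ptv_size
        in_sector = np.abs(np.arctan2(np.sin(ang - phi_c), np.cos(ang - phi_c))) <= half_w
        skin = 0.04
        ptv = in_sector & (r <= 1.0 - skin) & (r >= 1.0 - skin - thickness) & body
        ptv &= ~(lung_left | lung_right | heart)

        masks["body"][z] = body
        masks["heart"][z] = heart
        if laterality == "left":
            masks["lung_ipsi"][z], masks["lung_contra"][z] = lung_left, lung_right
        else:
            masks["lung_ipsi"][z], masks["lung_contra"][z] = lung_right, lung_left
        masks["ptv_breast"][z] = ptv

        if node_positive and z >= nz - 4:
            nodes = _ellipse(yy, xx, cy - 0.30 * ny, cx + sgn * 0.10 * nx,
                             0.055 * ny, 0.065 * nx) & body
            nodes &= ~(lung_left | lung_right | heart)
            masks["ptv_nodes"][z] = nodes

        hu = np.full((ny, nx), -1000.0)
        hu[body] = 20.0
        hu[lung_left | lung_right] = -700.0
        ct[z] = hu

    if not node_positive:
        del masks["ptv_nodes"]
    noise_rng = np.random.default_rng(noise_seed)
    ct += noise_rng.normal(0.0, 20.0, ct.shape).astype(np.float32) * (masks["body"] > 0)

    dxy = 3.0
    case = PatientCase(
        case_id=case_id,
        ct=ct.astype(np.float32),
        voxel_spacing=(dxy, dxy, slice_thickness_mm),
        masks=masks,
        laterality=laterality,
        prescription_dose=PRESCRIPTION_GY,
        institution=institution,
        covariates=dict(
            heart_proximity=proximity,
            curvature=curvature,
            ptv_size=ptv_size,
            node_positive=node_positive,
        ),
    )
    return case.validate()


# ---------------------------------------------------------------------------
# dose engines
# ---------------------------------------------------------------------------

def _corridor_geometry(case: PatientCase):
    """Tangential-corridor slab for a case.

    The opposed beams run perpendicular to the radial direction from the
    body centre to the PTV centroid, i.e. tangent to the chest wall at the
    breast.  The slab is the PTV's extent along that radial direction: its
    deep edge sits just below the deepest PTV voxel (the clinical "tangent
    clipping the chest wall"), its outer edge just beyond the skin surface
    of the PTV.  Returns (centroid_yx_vox, outward_normal_yx, dmin_mm,
    dmax_mm) with d measured from the PTV centroid, or None for an empty
    PTV.
    """
    ptv_proj = case.masks["ptv_breast"].any(axis=0)
    if not ptv_proj.any():
        return None
    dx, dy, _ = case.voxel_spacing
    body_proj = case.masks["body"].any(axis=0)
    ys, xs = np.nonzero(ptv_proj)
    cy_b, cx_b = (np.array(np.nonzero(body_proj)).mean(axis=1))
    cy_p, cx_p = ys.mean(), xs.mean()
    n = np.array([cy_p - cy_b, cx_p - cx_b])
    n /= np.linalg.norm(n) + 1e-12
    d = ((ys - cy_p) * n[0] + (xs - cx_p) * n[1]) * dy  # mm, dy == dx
    return (cy_p, cx_p), n, float(d.min()), float(d.max())


def _merge_params(engine_params):
    params = dict(DEFAULT_ENGINE_PARAMS)
    if engine_params:
        unknown = set(engine_params) - set(params)
        if unknown:
            raise ValidationError(f"unknown engine parameters: {sorted(unknown)}")
        params.update(engine_params)
    return params


def simulate_dose_3dcrt(case: PatientCase, engine_params: dict | None = None) -> DoseMap:
    """Analytic tangential-field plan: corridor slab + Gaussian penumbra."""
    p = _merge_params(engine_params)
    case.validate()
    nz, ny, nx = case.shape
    dose = np.zeros(case.shape, dtype=np.float32)
    geo = _corridor_geometry(case)
    if geo is not None:
        (cy_p, cx_p), n, dmin, dmax = geo
        lo = dmin - p["corridor_margin_mm"]
        hi = dmax + p["corridor_margin_mm"]
        sigma = p["penumbra_sigma_mm"]
        dx = case.voxel_spacing[0]
        yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
        d = ((yy - cy_p) * n[0] + (xx - cx_p) * n[1]) * dx  # signed mm from axis
        outside = np.maximum(np.maximum(lo - d, d - hi), 0.0)
        rel = np.exp(-outside ** 2 / (2.0 * sigma ** 2))
        inside = (d >= lo) & (d <= hi)
        # wedge-compensated in-field profile, continuous at the field edges
        u = np.clip((d - lo) / max(hi - lo, 1e-9), 0.0, 1.0)
        rel = np.where(inside, 1.0 + p["crt_ripple"] * np.sin(np.pi * u), rel)
        slice_dose = (case.prescription_dose * rel).astype(np.float32)
        for z in range(nz):
            dose[z] = slice_dose * case.masks["body"][z]
    return DoseMap(dose, case.voxel_spacing, "3DCRT", case.case_id).validate(case)


def simulate_dose_imrt(case: PatientCase, engine_params: dict | None = None) -> DoseMap:
    """Analytic IMRT plan: PTV-conformal high dose + soft-tissue low-dose bath."""
    p = _merge_params(engine_params)
    case.validate()
    nz, ny, nx = case.shape
    dx, dy, _ = case.voxel_spacing
    sigma = p["penumbra_sigma_mm"]
    presc = case.prescription_dose
    dose = np.zeros(case.shape, dtype=np.float32)
    lung = case.masks["lung_ipsi"] | case.masks["lung_contra"]
    heart = case.masks["heart"]
    for z in range(nz):
        body = case.masks["body"][z].astype(bool)
        ptv = case.masks["ptv_breast"][z].astype(bool)
        if ptv.any():
            d_ptv = ndimage.distance_transform_edt(~ptv, sampling=(dy, dx))
            high = presc * np.exp(-d_ptv ** 2 / (2.0 * sigma ** 2))
        else:
            high = np.zeros((ny, nx))
        bath = np.full((ny, nx), p["imrt_bath_gy"])
        bath[lung[z].astype(bool)] = p["imrt_bath_gy"] * p["imrt_bath_lung_factor"]
        bath[heart[z].astype(bool)] = p["imrt_bath_gy"] * p["imrt_bath_heart_factor"]
        dose[z] = (np.maximum(high, bath) * body).astype(np.float32)
    return DoseMap(dose, case.voxel_spacing, "IMRT", case.case_id).validate(case)


# ---------------------------------------------------------------------------
# cohort generation / labels
# ---------------------------------------------------------------------------

def ground_truth_label(case: PatientCase, dose_crt: DoseMap) -> str:
    """Technique an observer applying the OAR constraints to the simulated
    3D-CRT plan would choose (3D-CRT by default when it passes)."""
    from .dvh_engine import extract_metrics
    from .decision import ConstraintSet, check_constraints

    metrics = {
        "lung": extract_metrics(dose_crt, case.masks["lung_ipsi"], case.prescription_dose,
                                voxel_spacing=case.voxel_spacing, structure="lung"),
        "heart": extract_metrics(dose_crt, case.masks["heart"], case.prescription_dose,
                                 voxel_spacing=case.voxel_spacing, structure="heart"),
    }
    ok, _ = check_constraints(metrics, ConstraintSet())
    return "3DCRT" if ok else "IMRT"


def generate_cohort(spec: CohortSpec, engine_params: dict | None = None) -> list[CohortEntry]:
    """Generate all cases of a cohort with paired plans and truth labels."""
    spec.validate()
    entries = []
    for i in range(spec.n_cases):
        case = generate_case(spec, i)
        crt = simulate_dose_3dcrt(case, engine_params)
        imrt = simulate_dose_imrt(case, engine_params)
        entries.append(CohortEntry(case, crt, imrt, ground_truth_label(case, crt)))
    return entries


# ---------------------------------------------------------------------------
# persistence (npz per case + TSV manifest)
# ---------------------------------------------------------------------------

def save_cohort(entries, out_dir):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in entries:
        c = e.case
        arrays = {"ct": c.ct, "dose_3dcrt": e.dose_3dcrt.values,
                  "dose_imrt": e.dose_imrt.values}
        arrays.update({f"mask_{k}": v for k, v in c.masks.items()})
        np.savez_compressed(out_dir / f"{c.case_id}.npz", **arrays)
        meta = dict(case_id=c.case_id, institution=c.institution,
                    laterality=c.laterality, prescription_dose=c.prescription_dose,
                    voxel_spacing=list(c.voxel_spacing), label=e.label,
                    covariates=c.covariates)
        (out_dir / f"{c.case_id}.json").write_text(json.dumps(meta, indent=1))
        rows.append((c.case_id, c.institution, c.laterality, e.label,
                     int(c.masks["ptv_breast"].sum()), "ptv_nodes" in c.masks))
    with open(out_dir / "manifest.tsv", "w") as fh:
        fh.write("case_id\tinstitution\tlaterality\tlabel\tptv_voxels\tnode_positive\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")
    return out_dir / "manifest.tsv"


def load_cohort(out_dir) -> list[CohortEntry]:
    out_dir = Path(out_dir)
    entries = []
    import csv
    with open(out_dir / "manifest.tsv") as fh:
        case_ids = [row["case_id"] for row in csv.DictReader(fh, delimiter="\t")]
    for cid in case_ids:
        meta = json.loads((out_dir / f"{cid}.json").read_text())
        with np.load(out_dir / f"{cid}.npz") as data:
            masks = {k[5:]: data[k] for k in data.files if k.startswith("mask_")}
            spacing = tuple(meta["voxel_spacing"])
            case = PatientCase(cid, data["ct"], spacing, masks, meta["laterality"],
                               meta["prescription_dose"], meta["institution"],
                               meta["covariates"])
            crt = DoseMap(data["dose_3dcrt"], spacing, "3DCRT", cid)
            imrt = DoseMap(data["dose_imrt"], spacing, "IMRT", cid)
        entries.append(CohortEntry(case, crt, imrt, meta["label"]))
    return entries
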