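"""Synthetic cohorts, connectomes, and bundle phantoms with known effects.

Everything downstream of image preprocessing can be exercised without
patient data by simulating the three study conditions:

* a group-structured cohort (healthy controls and two white-matter-
  hyperintensity groups, one cognitively impaired) with lognormal lesion
  volumes, demographic covariates, and raw neuropsychological scores;
* per-subject 90-node connectomes derived from one distance-dependent
  base network, with the longest edges attenuated in the patient groups
  (WMH preferentially damages long association fibers);
* voxel direction-field phantoms (straight / curved / crossing bundles)
  for exercising the FACT tracker's termination rules.

A known linear mediation structure is implanted: a latent mediator
``M = a*X + covariate terms + noise`` (X = log lesion volume, standardized
within cohort) drives the edges incident to a designated mediator node, so
that the node's efficiency computed downstream is an almost deterministic
monotone image of ``M``; the memory outcome is ``Y = b*M + c'*X +
covariate terms + noise``. All randomness flows from one seeded generator,
so identical configurations are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import default_node_names
from .connectome import Connectome
from .tracking import DirectionField

GROUPS = ("HC", "WMH-no-CI", "WMH-CI")

# raw-score scale per test: (mean, sd, reversed) — reversed tests are timed,
# larger raw value = worse performance
TEST_SCALES: dict[str, tuple[float, float, bool]] = {
    "MMSE": (27.0, 2.0, False),
    "MoCA": (25.0, 2.0, False),
    "TMT-A": (60.0, 25.0, True),
    "TMT-B": (140.0, 50.0, True),
    "Stroop A": (30.0, 10.0, True),
    "Stroop B": (45.0, 12.0, True),
    "Stroop C": (80.0, 25.0, True),
    "CVF": (16.0, 4.0, False),
    "BNT": (22.0, 4.0, False),
    "AVLT-DDR": (5.0, 2.5, False),
    "VR-DR": (8.0, 3.5, False),
    "VR-C": (13.0, 1.5, False),
    "CDT": (3.2, 0.8, False),
}
MEMORY_TESTS = ("VR-DR", "AVLT-DDR")

# small covariate paths entering the implanted mediation model
# (standardized age, male indicator, standardized education)
_COV_M = (0.15, 0.05, -0.10)
_COV_Y = (-0.15, 0.05, 0.10)


@dataclass
class GroupWmhParams:
    """log10-normal volume parameters (ml) for one group.

    Total volume is the sum of the periventricular and deep draws, which
    guarantees ``twmh >= pwmh`` and ``twmh >= dwmh``.
    """

    pwmh_log10_mean: float
    pwmh_log10_sd: float
    dwmh_log10_mean: float
    dwmh_log10_sd: float


@dataclass
class GroupCovariateParams:
    age_mean: float
    age_sd: float
    male_prob: float
    edu_mean: float
    edu_sd: float


@dataclass
class MediationParams:
    """Structural coefficients of the implanted X -> M -> Y model.

    Default signs follow the lesion direction: higher lesion load lowers
    the mediator node's efficiency (a < 0), higher efficiency predicts
    better memory (b > 0), and the direct lesion effect on memory is
    negative (c' < 0), so the implant reinforces rather than offsets the
    lesion-induced loss of global efficiency.
    """

    a: float = -0.4
    b: float = 0.4
    c_prime: float = -0.1
    noise_sd: float = 0.5
    x_variable: str = "lg_twmh"   # lg_twmh | lg_pwmh | lg_dwmh
    mediator_node: int | None = None  # default: IFGoperc.L for 90 nodes, else 0
    implant_gain: float = 0.3     # edge scaling per unit latent mediator


# per-group defaults emulating an elderly WMH cohort: patient lesion loads
# several-fold above controls, slightly older / less-educated patients
DEFAULT_WMH_PARAMS = {
    "HC": GroupWmhParams(0.10, 0.15, -0.48, 0.25),
    "WMH-no-CI": GroupWmhParams(0.67, 0.15, 0.08, 0.25),
    "WMH-CI": GroupWmhParams(0.73, 0.15, 0.25, 0.30),
}
DEFAULT_COVARIATE_PARAMS = {
    "HC": GroupCovariateParams(63.2, 6.6, 0.48, 12.0, 3.5),
    "WMH-no-CI": GroupCovariateParams(66.4, 6.9, 0.36, 11.5, 3.5),
    "WMH-CI": GroupCovariateParams(67.8, 6.8, 0.46, 9.0, 3.0),
}
# group shift of the general-cognition latent driving non-memory tests
_COGNITION_SHIFT = {"HC": 0.0, "WMH-no-CI": -0.05, "WMH-CI": -0.9}
_MOCA_MEAN = {"HC": 26.5, "WMH-no-CI": 26.0, "WMH-CI": 21.0}


@dataclass
class CohortConfig:
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 52, "WMH-no-CI": 42, "WMH-CI": 41})
    n_nodes: int = 90
    base_density: float = 0.3
    edge_attenuation: float = 0.6
    lesioned_edge_fraction: float = 0.25
    wmh_params: dict[str, GroupWmhParams] = field(
        default_factory=lambda: dict(DEFAULT_WMH_PARAMS))
    covariate_params: dict[str, GroupCovariateParams] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    mediation_params: MediationParams = field(default_factory=MediationParams)
    fn_noise_sd: float = 0.08
    fa_noise_sd: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        for g in GROUPS:
            if g not in self.n_per_group:
                raise ValueError(f"n_per_group missing group {g!r}")
            if self.n_per_group[g] < 2:
                raise ValueError("every group needs at least 2 subjects")
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be at least 3")
        if not 0 < self.base_density <= 1:
            raise ValueError("base_density must lie in (0, 1]")
        if not 0 < self.edge_attenuation <= 1:
            raise ValueError("edge_attenuation must lie in (0, 1]")
        if not 0 <= self.lesioned_edge_fraction <= 1:
            raise ValueError("lesioned_edge_fraction must lie in [0, 1]")

    def null_configuration(self) -> "CohortConfig":
        """A copy with no group effect anywhere (exchangeable groups)."""
        hc_wmh = self.wmh_params["HC"]
        hc_cov = self.covariate_params["HC"]
        return replace(
            self,
            edge_attenuation=1.0,
            wmh_params={g: hc_wmh for g in GROUPS},
            covariate_params={g: hc_cov for g in GROUPS},
            mediation_params=replace(self.mediation_params, a=0.0, b=0.0,
                                     c_prime=0.0),
        )


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str            # "M" / "F"
    education: float    # years
    twmh: float         # ml
    pwmh: float
    dwmh: float
    raw_scores: dict[str, float]


def generate_base_connectome(n_nodes: int, base_density: float,
                             seed: int) -> Connectome:
    """Distance-dependent random geometric connectome on the unit cube.

    Nodes are placed uniformly in [0,1]^3 and exactly
    ``round(base_density * n(n-1)/2)`` edges are sampled without
    replacement with probability decaying in Euclidean distance, so long
    edges are present but rarer — these are the lesion candidates. Fiber
    counts fall with distance (minimum 4, surviving the FN > 3 threshold
    at full strength), FA falls mildly with distance, and fiber length is
    the straight-line distance in mm.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be at least 3")
    if not 0 < base_density <= 1:
        raise ValueError("base_density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(n_nodes, 3))
    iu, ju = np.triu_indices(n_nodes, 1)
    dist = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    n_pairs = iu.size
    n_edges = max(1, round(base_density * n_pairs))
    prob = np.exp(-dist / 0.3)
    prob /= prob.sum()
    chosen = rng.choice(n_pairs, size=n_edges, replace=False, p=prob)

    fn = np.zeros((n_nodes, n_nodes))
    fa = np.zeros((n_nodes, n_nodes))
    length = np.zeros((n_nodes, n_nodes))
    d_sel = dist[chosen]
    fn_sel = 4 + rng.poisson(28.0 * np.exp(-2.5 * d_sel))
    fa_sel = np.clip(rng.normal(0.5 - 0.1 * d_sel, 0.05), 0.05, 0.95)
    for idx, edge in enumerate(chosen):
        i, j = iu[edge], ju[edge]
        fn[i, j] = fn[j, i] = fn_sel[idx]
        fa[i, j] = fa[j, i] = fa_sel[idx]
        length[i, j] = length[j, i] = 100.0 * d_sel[idx]
    return Connectome(node_names=default_node_names(n_nodes), fn=fn,
                      fa_mean=fa, length_mean=length)


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=0)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def generate_mediation_dataset(a: float, b: float, c_prime: float,
                               noise_sd: float, n: int, seed: int,
                               covariate_effects: bool = True) -> pd.DataFrame:
    """Draw (x, m, y, covariates) directly from the structural model.

    ``x`` is standard normal; ``m = a*x + cov + noise`` and
    ``y = b*m + c'*x + cov + noise`` with independent Gaussian noise of
    scale ``noise_sd``. Used for calibration and recovery simulations at
    the statistics level.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    age = rng.normal(66.0, 7.0, n)
    sex = (rng.random(n) < 0.45).astype(float)
    edu = np.clip(np.round(rng.normal(11.0, 3.5, n)), 1, 22)
    if covariate_effects:
        zs = (_standardize(age), sex, _standardize(edu))
        cov_m = sum(c * z for c, z in zip(_COV_M, zs))
        cov_y = sum(c * z for c, z in zip(_COV_Y, zs))
    else:
        cov_m = cov_y = 0.0
    m = a * x + cov_m + noise_sd * rng.standard_normal(n)
    y = b * m + c_prime * x + cov_y + noise_sd * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "m": m, "y": y, "age": age, "sex": sex,
                         "education": edu})


def _lesion_mask(base: Connectome, fraction: float,
                 exclude_node: int) -> np.ndarray:
    """Longest `fraction` of base edges by length, sparing the mediator node."""
    n = base.n_nodes
    iu, ju = np.triu_indices(n, 1)
    present = base.fn[iu, ju] > 0
    spared = (iu == exclude_node) | (ju == exclude_node)
    candidates = np.nonzero(present & ~spared)[0]
    n_lesion = int(round(fraction * candidates.size))
    order = candidates[np.argsort(-base.length_mean[iu, ju][candidates],
                                  kind="stable")]
    mask = np.zeros((n, n), dtype=bool)
    for edge in order[:n_lesion]:
        i, j = iu[edge], ju[edge]
        mask[i, j] = mask[j, i] = True
    return mask


def generate_cohort(config: CohortConfig):
    """Generate subject records and matching per-subject connectomes.

    Returns ``(records, connectomes)`` where ``records`` is a list of
    :class:`SubjectRecord` and ``connectomes`` maps subject id to
    :class:`Connectome`.
    """
    rng = np.random.default_rng(config.seed)
    base = generate_base_connectome(
        config.n_nodes, config.base_density,
        seed=int(rng.integers(2**31 - 1)))
    med = config.mediation_params
    mediator = med.mediator_node
    if mediator is None:
        mediator = 10 if config.n_nodes == 90 else 0  # IFGoperc.L in AAL-90
    lesion = _lesion_mask(base, config.lesioned_edge_fraction, mediator)

    # pass 1: demographics and lesion volumes
    groups, ages, sexes, edus, pw, dw = [], [], [], [], [], []
    for g in GROUPS:
        cv = config.covariate_params[g]
        wp = config.wmh_params[g]
        for _ in range(config.n_per_group[g]):
            groups.append(g)
            ages.append(rng.normal(cv.age_mean, cv.age_sd))
            sexes.append("M" if rng.random() < cv.male_prob else "F")
            edus.append(float(np.clip(np.round(rng.normal(cv.edu_mean,
                                                          cv.edu_sd)), 1, 22)))
            pw.append(10.0 ** rng.normal(wp.pwmh_log10_mean, wp.pwmh_log10_sd))
            dw.append(10.0 ** rng.normal(wp.dwmh_log10_mean, wp.dwmh_log10_sd))
    pw, dw = np.asarray(pw), np.asarray(dw)
    tw = pw + dw
    n_sub = tw.size

    lg = {"lg_twmh": np.log10(tw), "lg_pwmh": np.log10(pw),
          "lg_dwmh": np.log10(dw)}
    if med.x_variable not in lg:
        raise ValueError(f"unknown x_variable {med.x_variable!r}")
    x_std = _standardize(lg[med.x_variable])
    age_std = _standardize(ages)
    sex01 = np.asarray([1.0 if s == "M" else 0.0 for s in sexes])
    edu_std = _standardize(edus)
    cov_m = _COV_M[0] * age_std + _COV_M[1] * sex01 + _COV_M[2] * edu_std
    cov_y = _COV_Y[0] * age_std + _COV_Y[1] * sex01 + _COV_Y[2] * edu_std

    m_lat = med.a * x_std + cov_m + med.noise_sd * rng.standard_normal(n_sub)
    y_lat = (med.b * m_lat + med.c_prime * x_std + cov_y
             + med.noise_sd * rng.standard_normal(n_sub))

    iu, ju = np.triu_indices(config.n_nodes, 1)
    base_fn_u = base.fn[iu, ju]
    records: list[SubjectRecord] = []
    connectomes: dict[str, Connectome] = {}
    # pass 2: raw scores and connectomes, in the same fixed subject order
    for s in range(n_sub):
        g = groups[s]
        cog = _COGNITION_SHIFT[g] + 0.6 * rng.standard_normal()
        scores: dict[str, float] = {}
        for test, (mu, sd, reversed_) in TEST_SCALES.items():
            if test == "MoCA":
                val = _MOCA_MEAN[g] + 1.5 * rng.standard_normal()
                scores[test] = float(np.clip(np.round(val), 0, 30))
                continue
            if test in MEMORY_TESTS:
                latent = y_lat[s] + 0.15 * rng.standard_normal()
            else:
                latent = cog + 0.5 * rng.standard_normal()
            signed = -latent if reversed_ else latent
            scores[test] = float(mu + sd * signed)

        noise = np.exp(rng.normal(0.0, config.fn_noise_sd, iu.size))
        fn_u = np.rint(base_fn_u * noise)
        fa_jit = rng.normal(0.0, config.fa_noise_sd, iu.size)
        fn = np.zeros_like(base.fn)
        fa = np.zeros_like(base.fa_mean)
        fn[iu, ju] = fn[ju, iu] = fn_u
        fa[iu, ju] = fa[ju, iu] = np.where(
            base.fa_mean[iu, ju] > 0,
            np.clip(base.fa_mean[iu, ju] + fa_jit, 0.05, 0.95), 0.0)
        if g != "HC":
            fn[lesion] = np.rint(fn[lesion] * config.edge_attenuation)
            fa[lesion] *= config.edge_attenuation
        # mediator implant: incident edges track the latent mediator exactly
        scale = max(0.2, 1.0 + med.implant_gain * m_lat[s])
        fn[mediator, :] = np.rint(base.fn[mediator, :] * scale)
        fn[:, mediator] = fn[mediator, :]
        fa[mediator, :] = base.fa_mean[mediator, :]
        fa[:, mediator] = fa[mediator, :]

        support = fn > 0
        fa = np.where(support, fa, 0.0)
        length = np.where(support, base.length_mean, 0.0)
        sid = f"sub-{s + 1:03d}"
        records.append(SubjectRecord(
            subject_id=sid, group=g, age=round(float(ages[s]), 1),
            sex=sexes[s], education=float(edus[s]),
            twmh=float(tw[s]), pwmh=float(pw[s]), dwmh=float(dw[s]),
            raw_scores=scores))
        connectomes[sid] = Connectome(node_names=list(base.node_names),
                                      fn=fn, fa_mean=fa, length_mean=length)
    return records, connectomes


def cohort_to_dataframe(records: list[SubjectRecord]) -> pd.DataFrame:
    """One row per subject: demographics, lesion volumes, raw test scores."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, "age": r.age,
               "sex": r.sex, "education": r.education, "twmh": r.twmh,
               "pwmh": r.pwmh, "dwmh": r.dwmh}
        row.update(r.raw_scores)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BundlePhantom:
    """A direction-field phantom with labeled end-regions."""

    field: DirectionField
    end_labels: np.ndarray   # 0 background, 1..k end-region labels
    bundle_mask: np.ndarray


def generate_direction_field(geometry: str, grid_shape: tuple[int, int, int],
                             fa_inside: float = 0.7, fa_outside: float = 0.1,
                             seed: int = 0) -> BundlePhantom:
    """Deterministic bundle phantoms for the tracker.

    ``straight_bundle`` — a tube along axis 0 between end regions 1 and 2.
    ``curved_bundle``   — a quarter-circle arc in the xy plane whose
    per-voxel tangent turns a few degrees per step.
    ``crossing``        — two orthogonal straight bundles; in the overlap
    the stored direction is the first bundle's, i.e. 90 degrees off the
    second bundle's course. The ``seed`` argument is accepted for API
    uniformity; the phantoms are analytic and use no randomness.
    """
    if not fa_inside > fa_outside >= 0:
        raise ValueError("need fa_inside > fa_outside >= 0")
    nx, ny, nz = (int(v) for v in grid_shape)
    directions = np.zeros((nx, ny, nz, 3))
    directions[..., 0] = 1.0  # unit vectors everywhere (sign/axis arbitrary)
    fa = np.full((nx, ny, nz), float(fa_outside))
    labels = np.zeros((nx, ny, nz), dtype=np.int32)

    def _band(n: int) -> np.ndarray:
        c = n // 2
        return np.abs(np.arange(n) - c) <= max(1, n // 6)

    if geometry == "straight_bundle":
        if nx < 5 or ny < 3 or nz < 3:
            raise ValueError("grid too small for a straight bundle (min 5x3x3)")
        mask = np.zeros((nx, ny, nz), dtype=bool)
        mask[:, _band(ny)[:, None] & _band(nz)[None, :]] = True
        fa[mask] = fa_inside
        labels[:2][mask[:2]] = 1
        labels[nx - 2:][mask[nx - 2:]] = 2
    elif geometry == "curved_bundle":
        if nx < 12 or ny < 12 or nz < 3:
            raise ValueError("grid too small for a curved bundle (min 12x12x3)")
        radius = 0.7 * min(nx, ny)
        xs = np.arange(nx) + 0.5
        ys = np.arange(ny) + 0.5
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        r = np.hypot(X, Y)
        theta = np.degrees(np.arctan2(Y, X))
        in_arc = (np.abs(r - radius) <= 1.5) & (theta >= 0) & (theta <= 90)
        zband = _band(nz)
        mask = in_arc[:, :, None] & zband[None, None, :]
        fa[mask] = fa_inside
        tangent = np.stack([-np.sin(np.radians(theta)),
                            np.cos(np.radians(theta)),
                            np.zeros_like(theta)], axis=-1)
        directions[mask] = np.broadcast_to(
            tangent[:, :, None, :], (nx, ny, nz, 3))[mask]
        labels[mask & (theta <= 8)[:, :, None]] = 1
        labels[mask & (theta >= 82)[:, :, None]] = 2
    elif geometry == "crossing":
        if nx < 9 or ny < 9 or nz < 3:
            raise ValueError("grid too small for crossing bundles (min 9x9x3)")
        zband = _band(nz)
        mask_a = np.zeros((nx, ny, nz), dtype=bool)
        mask_a[:, _band(ny)[:, None] & zband[None, :]] = True
        mask_b = np.zeros((nx, ny, nz), dtype=bool)
        mask_b[_band(nx)[:, None, None]
               & np.ones(ny, bool)[None, :, None]
               & zband[None, None, :]] = True
        fa[mask_a | mask_b] = fa_inside
        directions[mask_b] = (0.0, 1.0, 0.0)
        directions[mask_a] = (1.0, 0.0, 0.0)  # overlap stores bundle A
        labels[:2][mask_a[:2]] = 1
        labels[nx - 2:][mask_a[nx - 2:]] = 2
        labels[:, :2][mask_b[:, :2]] = 3
        labels[:, ny - 2:][mask_b[:, ny - 2:]] = 4
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    field = DirectionField(directions=directions, fa=fa)
    mask_out = fa >= fa_inside
    return BundlePhantom(field=field, end_labels=labels, bundle_mask=mask_out)
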