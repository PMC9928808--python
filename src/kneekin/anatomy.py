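"""Anatomical frame construction and joint-coordinate-system kinematics.

Bone-fixed frames are built from surface geometry: the femoral flexion
axis from a cylinder fitted to the posterior/distal condyles, long-bone
axes from cones fitted to the diaphyses, and the patellar frame from the
principal axes of inertia.  Relative bone poses are decomposed into the
six joint parameters of a two-fixed-axes + floating-axis convention: one
axis fixed in the parent bone (femoral X), one fixed in the child (tibial
or patellar Z) and a floating axis perpendicular to both.

Translations are reported as the components of the parent-to-child origin
vector in the (generally oblique) basis formed by the two fixed axes and
the floating axis, i.e. the unique (q1, q2, q3) with
``d = q1*e1 + q2*e2 + q3*e3``.  This makes decomposition and composition
exact inverses and means a fixed offset of the child origin along the
child axis shifts exactly one translation channel.

All rotations are in degrees and all lengths in millimetres.  Sign
conventions (which rotation direction is "positive") are carried by
:class:`JointSpec` and default to +1 for every parameter on a right knee
with the parent X axis pointing right; mirror left-knee data before
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

_EPS_ORTHO = 1e-9
_SINGULARITY_DEG = 0.1


# --------------------------------------------------------------------------
# frames and rigid transforms
# --------------------------------------------------------------------------


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"{what} has (near-)zero length")
    return v / n


@dataclass
class BoneFrame:
    """Origin and right-handed orthonormal axes of a bone-fixed frame.

    ``axes`` holds the X, Y, Z direction vectors as columns, expressed in
    lab coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-8):
            raise ValueError("frame axes are not orthonormal")
        if np.dot(np.cross(self.axes[:, 0], self.axes[:, 1]), self.axes[:, 2]) < 0:
            raise ValueError("frame axes are not right-handed (X x Y != Z)")

    @classmethod
    def from_axes(cls, origin, x, y, z) -> "BoneFrame":
        return cls(origin=np.asarray(origin, float), axes=np.column_stack([x, y, z]))

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous lab-from-bone transform."""
        T = np.eye(4)
        T[:3, :3] = self.axes
        T[:3, 3] = self.origin
        return T

    def transformed(self, T: np.ndarray) -> "BoneFrame":
        """Frame after rigid motion ``T`` (4x4) of the underlying bone."""
        T = np.asarray(T, dtype=float)
        return BoneFrame(
            origin=T[:3, :3] @ self.origin + T[:3, 3], axes=T[:3, :3] @ self.axes
        )


def rigid_transform(rotation: np.ndarray | None = None, translation=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Build a 4x4 homogeneous transform from a 3x3 rotation and translation."""
    T = np.eye(4)
    if rotation is not None:
        T[:3, :3] = np.asarray(rotation, dtype=float)
    T[:3, 3] = np.asarray(translation, dtype=float)
    return T


def _apply(T: np.ndarray, points: np.ndarray) -> np.ndarray:
    return points @ T[:3, :3].T + T[:3, 3]


# --------------------------------------------------------------------------
# surface primitive fits
# --------------------------------------------------------------------------


@dataclass
class CylinderFit:
    axis: np.ndarray       # unit direction
    point: np.ndarray      # a point on the axis
    radius: float
    rms_residual: float


@dataclass
class ConeFit:
    axis: np.ndarray       # unit direction, data lie on the positive side
    apex: np.ndarray
    half_angle_deg: float
    rms_residual: float


class SurfaceFitError(RuntimeError):
    """Degenerate input or non-convergence of a surface fit."""


def _check_nondegenerate(points: np.ndarray, min_points: int, what: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{what}: points must be an (n, 3) array")
    if pts.shape[0] < min_points:
        raise SurfaceFitError(f"{what}: need at least {min_points} points, got {pts.shape[0]}")
    s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if s[2] < 1e-9 * max(s[0], 1.0):
        raise SurfaceFitError(f"{what}: points are coplanar or collinear")
    return pts


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-magnitude component made positive."""
    idx = int(np.argmax(np.abs(v)))
    return -v if v[idx] < 0 else v


def _dir_from_angles(theta: float, phi: float) -> np.ndarray:
    st, ct = np.sin(theta), np.cos(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), ct])


def _angles_from_dir(w: np.ndarray) -> tuple[float, float]:
    w = _unit(w)
    return float(np.arccos(np.clip(w[2], -1, 1))), float(np.arctan2(w[1], w[0]))


def _perp_basis(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(w, a))
    return u, np.cross(w, u)


def _circle_fit_cost(xy: np.ndarray) -> float:
    """RMS residual of an algebraic (Kasa) circle fit to 2-D points."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    try:
        (a, b, c), *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
    except np.linalg.LinAlgError:
        return np.inf
    r2 = c + a**2 + b**2
    if r2 <= 0:
        return np.inf
    r = np.sqrt((x - a) ** 2 + (y - b) ** 2) - np.sqrt(r2)
    return float(np.sqrt(np.mean(r**2)))


def _axis_direction_search(centered: np.ndarray, n_dirs: int = 200) -> np.ndarray:
    """Coarse cylinder-axis estimate: best circle fit over a hemisphere.

    A partial (e.g. half-arc) patch makes the principal directions of the
    point cloud unreliable, so the axis is found by scanning a Fibonacci
    hemisphere of candidate directions and scoring the algebraic circle
    fit of the projection perpendicular to each.
    """
    k = np.arange(n_dirs)
    z = (k + 0.5) / n_dirs                      # upper hemisphere only
    phi = np.pi * (1 + np.sqrt(5.0)) * k
    dirs = np.column_stack(
        [np.sqrt(1 - z**2) * np.cos(phi), np.sqrt(1 - z**2) * np.sin(phi), z]
    )
    best, best_cost = dirs[0], np.inf
    for w in dirs:
        u, v = _perp_basis(w)
        cost = _circle_fit_cost(centered @ np.column_stack([u, v]))
        if cost < best_cost:
            best, best_cost = w, cost
    return best


def fit_cylinder(points, *, max_iter: int = 200) -> CylinderFit:
    """Orthogonal-distance least-squares cylinder fit.

    Returns the unit axis direction (sign convention: the
    largest-magnitude component is positive), a point on the axis in the
    plane of the centroid, and the radius.  Raises
    :class:`SurfaceFitError` for coplanar/collinear points or
    non-convergence.
    """
    pts = _check_nondegenerate(points, 6, "fit_cylinder")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)

    def unpack(p):
        w = _dir_from_angles(p[0], p[1])
        u, v = _perp_basis(w)
        c = centroid + p[2] * u + p[3] * v
        return w, c, p[4]

    def resid(p):
        w, c, r = unpack(p)
        d = pts - c
        perp = d - np.outer(d @ w, w)
        return np.linalg.norm(perp, axis=1) - r

    # a partial patch can make the along-axis direction any of the three
    # principal directions, so start from each (plus a coarse hemisphere
    # search) and keep the best fit
    sol = None
    for w0 in (*vt, _axis_direction_search(centered)):
        theta0, phi0 = _angles_from_dir(w0)
        perp = centered - np.outer(centered @ w0, w0)
        r0 = float(np.linalg.norm(perp, axis=1).mean())
        cand = least_squares(
            resid,
            x0=np.array([theta0, phi0, 0.0, 0.0, r0]),
            method="lm",
            xtol=1e-13,
            ftol=1e-13,
            max_nfev=max_iter * 20,
        )
        if cand.success and (sol is None or cand.cost < sol.cost):
            sol = cand
    if sol is None:
        raise SurfaceFitError(
            f"cylinder fit did not converge from any principal-direction start "
            f"(max {max_iter * 20} evaluations each)"
        )
    w, c, r = unpack(sol.x)
    if r <= 0:
        raise SurfaceFitError("cylinder fit converged to a non-positive radius")
    w = _canonical_sign(w)
    res = resid(sol.x)
    return CylinderFit(axis=w, point=c, radius=float(r),
                       rms_residual=float(np.sqrt(np.mean(res**2))))


def fit_cone(points, *, max_iter: int = 200) -> ConeFit:
    """Orthogonal-distance least-squares cone fit.

    The axis is oriented so the data lie on its positive side (from apex
    toward the points).  A near-zero half-angle (cylinder-like data) is
    reported, not an error; callers needing a true cone should inspect
    ``half_angle_deg``.
    """
    pts = _check_nondegenerate(points, 6, "fit_cone")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    w0 = vt[0]
    t = centered @ w0
    rho = np.linalg.norm(centered - np.outer(t, w0), axis=1)
    # slope of radius along the axis gives the opening angle and apex
    A = np.column_stack([np.ones_like(t), t])
    (rho0, slope), *_ = np.linalg.lstsq(A, rho, rcond=None)
    if slope < 0:  # make radius grow along +w0
        w0, t, slope = -w0, -t, -slope
    alpha0 = float(np.arctan(max(slope, 1e-4)))
    t_apex = -rho0 / max(slope, 1e-4)
    apex0 = centroid + t_apex * w0

    def unpack(p):
        w = _dir_from_angles(p[0], p[1])
        return w, p[2:5], p[5]

    def resid(p):
        w, apex, alpha = unpack(p)
        d = pts - apex
        t = d @ w
        rho = np.linalg.norm(d - np.outer(t, w), axis=1)
        return rho * np.cos(alpha) - t * np.sin(alpha)

    theta0, phi0 = _angles_from_dir(w0)
    # near-cylindrical data push the apex far away and need many more
    # small LM steps than a well-conditioned cone
    sol = least_squares(
        resid,
        x0=np.array([theta0, phi0, *apex0, alpha0]),
        method="lm",
        xtol=1e-13,
        ftol=1e-13,
        max_nfev=max_iter * 40,
    )
    if not sol.success:
        raise SurfaceFitError(
            f"cone fit did not converge: {sol.message} (nfev={sol.nfev}, cost={sol.cost:.3e})"
        )
    w, apex, alpha = unpack(sol.x)
    if alpha < 0:
        alpha = -alpha
        w = -w  # keep data on the positive side
    t = (pts - apex) @ w
    if np.median(t) < 0:
        w = -w
    res = resid(sol.x)
    return ConeFit(
        axis=_unit(w),
        apex=np.asarray(apex, float),
        half_angle_deg=float(np.degrees(alpha)),
        rms_residual=float(np.sqrt(np.mean(res**2))),
    )


def principal_axes(geometry, *, hint_vectors=None, degeneracy_tol: float = 1e-6):
    """Centroid and principal axes of inertia of points or a closed mesh.

    ``geometry`` is an (n, 3) point array (unit point masses) or a
    ``trimesh.Trimesh`` (uniform solid).  Returns ``(centroid, axes,
    moments)`` with axes as columns ordered by ascending moment of
    inertia.  ``hint_vectors`` (one per axis, entries may be None) resolve
    the sign of each axis; otherwise the largest-magnitude component is
    made positive.  Nearly degenerate (spherical/cylindrical) inertia
    raises a ``SurfaceFitError``.
    """
    if hasattr(geometry, "moment_inertia") and hasattr(geometry, "center_mass"):
        centroid = np.asarray(geometry.center_mass, dtype=float)
        inertia = np.asarray(geometry.moment_inertia, dtype=float)
    else:
        pts = np.asarray(geometry, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
            raise ValueError("principal_axes: need an (n >= 4, 3) point array or a mesh")
        centroid = pts.mean(axis=0)
        d = pts - centroid
        r2 = (d**2).sum(axis=1)
        inertia = np.eye(3) * r2.sum() - d.T @ d
    moments, vecs = np.linalg.eigh(inertia)
    scale = max(abs(moments[2]), 1.0)
    gaps = np.diff(moments) / scale
    if (gaps < degeneracy_tol).any():
        raise SurfaceFitError(
            f"degenerate inertia tensor (moments {moments}); axes are ambiguous"
        )
    axes = []
    for i in range(3):
        v = vecs[:, i]
        hint = None if hint_vectors is None else hint_vectors[i]
        if hint is not None:
            if abs(np.dot(v, hint)) < 1e-12:
                raise ValueError(f"hint vector for axis {i} is perpendicular to the axis")
            v = v if np.dot(v, hint) > 0 else -v
        else:
            v = _canonical_sign(v)
        axes.append(v)
    axes = np.column_stack(axes)
    if np.linalg.det(axes) < 0:  # keep a right-handed triad without moving axis 0/1
        axes[:, 2] = -axes[:, 2]
    return centroid, axes, moments


# --------------------------------------------------------------------------
# bone frame constructions
# --------------------------------------------------------------------------


def build_femoral_frame(
    condyle_points,
    diaphysis_points,
    notch_apex,
    *,
    right_hint=None,
    proximal_hint=None,
) -> BoneFrame:
    """Femoral frame from condylar cylinder + diaphyseal cone + notch apex.

    X is the condylar cylinder axis (pointing right), Y = normalize(L1 x X)
    points anteriorly where L1 is the diaphyseal cone axis pointing
    proximally, Z = X x Y points proximally.  The origin is the foot of
    the perpendicular from the intercondylar notch apex onto the cylinder
    axis.
    """
    cyl = fit_cylinder(condyle_points)
    x = cyl.axis
    if right_hint is not None:
        x = x if np.dot(x, right_hint) > 0 else -x
    cone = fit_cone(diaphysis_points)
    l1 = cone.axis
    if proximal_hint is not None:
        l1 = l1 if np.dot(l1, proximal_hint) > 0 else -l1
    cross = np.cross(l1, x)
    if np.linalg.norm(cross) < np.sin(np.radians(_SINGULARITY_DEG)):
        raise ValueError("diaphyseal axis is (nearly) parallel to the condylar axis")
    y = _unit(cross)
    z = np.cross(x, y)
    apex = np.asarray(notch_apex, dtype=float)
    origin = cyl.point + np.dot(apex - cyl.point, x) * x
    return BoneFrame.from_axes(origin, x, y, z)


def build_tibial_frame(
    diaphysis_points,
    plateau_centers,
    eminence_midpoint,
    femoral_origin,
    *,
    proximal_hint=None,
    right_hint=None,
) -> BoneFrame:
    """Tibial frame from diaphyseal cone + plateau landmarks.

    Z is the diaphyseal cone axis pointing proximally, passing through the
    intercondylar eminence midpoint; Y = normalize(Z x L3) points
    anteriorly where L3 joins the two plateau centers pointing right;
    X = Y x Z points right.  The origin is the intersection of the Z line
    with the plane through the femoral origin perpendicular to Z (the
    femoral origin at the reference pose must be supplied).
    """
    cone = fit_cone(diaphysis_points)
    z = cone.axis
    if proximal_hint is not None:
        z = z if np.dot(z, proximal_hint) > 0 else -z
    p0, p1 = (np.asarray(p, dtype=float) for p in plateau_centers)
    if np.linalg.norm(p1 - p0) < 1e-9:
        raise ValueError("plateau centers coincide")
    l3 = _unit(p1 - p0)
    if right_hint is not None:
        l3 = l3 if np.dot(l3, right_hint) > 0 else -l3
    cross = np.cross(z, l3)
    if np.linalg.norm(cross) < np.sin(np.radians(_SINGULARITY_DEG)):
        raise ValueError("plateau line is (nearly) parallel to the tibial long axis")
    y = _unit(cross)
    x = np.cross(y, z)
    m = np.asarray(eminence_midpoint, dtype=float)
    of = np.asarray(femoral_origin, dtype=float)
    origin = m + np.dot(of - m, z) * z
    return BoneFrame.from_axes(origin, x, y, z)


def build_patellar_frame(points, ridge_direction, anterior_hint) -> BoneFrame:
    """Patellar frame from the inertia tensor and the posterior ridge.

    Y is the principal inertia axis with the largest moment (normal to the
    flat aspect of the bone), signed anteriorly by ``anterior_hint``;
    X = normalize(Y x ridge) points right for a superiorly directed ridge;
    Z = X x Y points superiorly.  The origin is the centroid.
    """
    centroid, axes, moments = principal_axes(points)
    y = axes[:, 2]  # largest moment
    y = y if np.dot(y, anterior_hint) > 0 else -y
    ridge = _unit(np.asarray(ridge_direction, dtype=float), "ridge direction")
    cross = np.cross(y, ridge)
    if np.linalg.norm(cross) < np.sin(np.radians(_SINGULARITY_DEG)):
        raise ValueError("ridge direction is (nearly) parallel to the anterior axis")
    x = _unit(cross)
    z = np.cross(x, y)
    return BoneFrame.from_axes(centroid, x, y, z)


# --------------------------------------------------------------------------
# joint coordinate system
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class JointSpec:
    """Convention of one joint's six-parameter decomposition.

    ``parameter_names`` orders the three translations (parent fixed axis,
    floating axis, child fixed axis) then the three rotations (parent
    fixed, floating, child fixed).  ``signs`` multiplies each reported
    parameter, defaulting to +1 everywhere (right-knee convention with
    the parent X axis pointing right).
    """

    name: str
    parameter_names: tuple[str, ...]
    signs: tuple[float, ...] = (1.0,) * 6

    def __post_init__(self):
        if len(self.parameter_names) != 6 or len(self.signs) != 6:
            raise ValueError("JointSpec needs 6 parameter names and 6 signs")


TF_JOINT_SPEC = JointSpec(
    name="tibiofemoral",
    parameter_names=(
        "tf_lateral_shift",      # along femoral X (parent fixed)
        "tf_anterior_drawer",    # along floating axis
        "tf_joint_distraction",  # along tibial Z (child fixed)
        "tf_flexion",            # about femoral X
        "tf_abduction",          # about floating axis
        "tf_external_rotation",  # about tibial Z
    ),
)

PF_JOINT_SPEC = JointSpec(
    name="patellofemoral",
    parameter_names=(
        "pf_lateral_shift",
        "pf_anterior_translation",
        "pf_superior_translation",
        "pf_flexion",
        "pf_lateral_rotation",
        "pf_lateral_tilt",
    ),
)


class JointSingularityError(ValueError):
    """Fixed axes (nearly) parallel: the floating axis is undefined."""


def _relative(parent_pose: np.ndarray, child_pose: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Rp, op = parent_pose[:3, :3], parent_pose[:3, 3]
    Rc, oc = child_pose[:3, :3], child_pose[:3, 3]
    return Rp.T @ Rc, Rp.T @ (oc - op)


def _jcs_axes(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    e1 = np.array([1.0, 0.0, 0.0])   # parent fixed X, parent coords
    e3 = R[:, 2]                      # child fixed Z, parent coords
    cross = np.cross(e3, e1)
    n = np.linalg.norm(cross)
    if n < np.sin(np.radians(_SINGULARITY_DEG)):
        raise JointSingularityError(
            "fixed axes are within 0.1 deg of parallel; floating axis undefined"
        )
    return e1, cross / n, e3


def jcs_decompose(parent_pose, child_pose, spec: JointSpec = TF_JOINT_SPEC) -> np.ndarray:
    """Six joint parameters (3 translations mm, 3 rotations deg) of a pose pair.

    Rotations are the intrinsic parent-X / floating-Y / child-Z angles
    (the floating-axis angle is reported as the angle between the fixed
    axes minus 90 deg); translations are the oblique-basis components of
    the parent-origin -> child-origin vector along (parent fixed,
    floating, child fixed) axes.
    """
    parent_pose = np.asarray(parent_pose, dtype=float)
    child_pose = np.asarray(child_pose, dtype=float)
    R, d = _relative(parent_pose, child_pose)
    e1, e2, e3 = _jcs_axes(R)
    a, b, c = Rotation.from_matrix(R).as_euler("XYZ", degrees=True)
    q = np.linalg.solve(np.column_stack([e1, e2, e3]), d)
    raw = np.array([q[0], q[1], q[2], a, -b, c])
    return raw * np.asarray(spec.signs)


def jcs_compose(params, spec: JointSpec = TF_JOINT_SPEC) -> np.ndarray:
    """Relative child-in-parent pose (4x4) whose decomposition is ``params``."""
    raw = np.asarray(params, dtype=float) / np.asarray(spec.signs)
    q1, q2, q3, flex, abd, ext = raw
    if not abs(abd) < 90.0 - _SINGULARITY_DEG:
        raise ValueError(f"floating-axis rotation {abd} deg out of range (|.| < 90)")
    R = Rotation.from_euler("XYZ", [flex, -abd, ext], degrees=True).as_matrix()
    e1, e2, e3 = _jcs_axes(R)
    d = q1 * e1 + q2 * e2 + q3 * e3
    return rigid_transform(R, d)


def jcs_decompose_trajectory(parent_poses, child_poses, spec: JointSpec) -> np.ndarray:
    return np.array(
        [jcs_decompose(p, c, spec) for p, c in zip(parent_poses, child_poses)]
    )


def reexpress_parameters(
    params_seq: np.ndarray,
    parent_offset: np.ndarray,
    child_offset: np.ndarray,
    spec: JointSpec = TF_JOINT_SPEC,
) -> np.ndarray:
    """Re-express a 6-parameter trajectory in shifted bone frames.

    ``parent_offset`` / ``child_offset`` are fixed 4x4 transforms mapping
    the NEW frame into the old one (new pose = old pose @ offset).  Each
    sample's relative pose is conjugated accordingly and re-decomposed:
    ``rel' = inv(parent_offset) @ rel @ child_offset``.
    """
    params_seq = np.atleast_2d(np.asarray(params_seq, dtype=float))
    A_inv = np.linalg.inv(np.asarray(parent_offset, dtype=float))
    B = np.asarray(child_offset, dtype=float)
    out = np.empty_like(params_seq)
    for i, params in enumerate(params_seq):
        rel = jcs_compose(params, spec)
        out[i] = jcs_decompose(np.eye(4), A_inv @ rel @ B, spec)
    return out


def reexpress_trajectory(trial, femur_offset, tibia_offset, patella_offset):
    """Re-express a trial's TF and PF channels in shifted bone frames.

    The femur is the parent of both joints; constant offset transforms are
    applied per bone and every sample is re-decomposed.  Returns a new
    :class:`kneekin.datamodel.KinematicTrial`.
    """
    import pandas as pd

    tf_cols = list(TF_JOINT_SPEC.parameter_names)
    pf_cols = list(PF_JOINT_SPEC.parameter_names)
    tf_new = reexpress_parameters(
        trial.samples[tf_cols].to_numpy(), femur_offset, tibia_offset, TF_JOINT_SPEC
    )
    pf_new = reexpress_parameters(
        trial.samples[pf_cols].to_numpy(), femur_offset, patella_offset, PF_JOINT_SPEC
    )
    samples = trial.samples.copy()
    samples.loc[:, tf_cols] = tf_new
    samples.loc[:, pf_cols] = pf_new
    return trial.with_samples(pd.DataFrame(samples, columns=trial.samples.columns))
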