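"""Co-registration of reference cross-sections into the circular cuff frame.

MicroCT-like and histology-like sections arrive distorted: fixed-tissue
shrinkage makes the nerve outline elliptical and the section is rotated
arbitrarily relative to the cuff.  Co-registration (i) fits the nerve
boundary, (ii) applies a per-axis rescaling that maps the fitted outline to
the circular nerve profile, (iii) rotates so the fiducial (cuff opening)
sits at 12 o'clock, and (iv) flips left-side nerves horizontally so all
nerves share one anatomical frame.  Fascicle centers of mass are then
expressed in the shared polar convention (deg clockwise from the fiducial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import EllipseModel, regionprops

from .conventions import polar_from_xy, theta_from_xy
from .recon import FascicleCoM
from .phantom import ReferenceImages


class CoregistrationError(RuntimeError):
    pass


@dataclass
class ReferenceSegmentation:
    """Segmented reference section in pixel coordinates (row/col image frame)."""

    boundary_px: np.ndarray  # (K, 2) (x=col, y=row) points on the nerve outline
    masks: dict[str, np.ndarray]  # binary fascicle masks, keyed by mask id
    mask_labels: dict[str, str]  # mask id -> anatomical label or "?"
    fiducial_px: tuple[float, float]
    pixel_size_um: float
    side: str = "right"
    modality: str = "microct"
    nerve_id: str = ""
    nerve_radius_um: float = 700.0


@dataclass
class RigidTransformSpec:
    """Composition (fixed order): per-axis scale → rotation → translation →
    optional horizontal flip.  Scales map the fitted elliptical outline onto
    the circular nerve profile; units end up in µm in the cuff frame."""

    scale_major: float
    scale_minor: float
    axis_angle_deg: float  # image-frame direction of the fitted major axis
    rotation_deg: float  # applied after scaling, to put the fiducial at 0°
    translation_um: tuple[float, float]
    flip_horizontal: bool = False
    residual_rms_um: float = 0.0


def fit_circle(boundary: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic (Kåsa) least-squares circle fit.

    Returns (center, radius, residual_rms).  Raises for < 3 points or
    collinear input.
    """
    pts = np.asarray(boundary, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 boundary points")
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("collinear boundary points; circle fit is singular")
    cx, cy = sol[0], sol[1]
    r = np.sqrt(sol[2] + cx**2 + cy**2)
    resid = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r
    return np.array([cx, cy]), float(r), float(np.sqrt(np.mean(resid**2)))


def fit_ellipse(mask: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    """Moments-based ellipse fit of a binary mask.

    Returns ((cx, cy) in (col, row) pixel coordinates, semi-major, semi-minor,
    orientation deg of the major axis CCW from the +x/col axis).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = regionprops(mask.astype(np.uint8))[0]
    cy, cx = props.centroid
    a = props.axis_major_length / 2.0
    b = props.axis_minor_length / 2.0
    # regionprops orientation: angle of major axis from the *row* axis, CCW
    theta = 90.0 - np.degrees(props.orientation)
    return (float(cx), float(cy)), float(a), float(b), float(theta)


def _fit_boundary_ellipse(pts: np.ndarray):
    model = EllipseModel.from_estimate(np.asarray(pts, dtype=float))
    if not model:
        raise CoregistrationError("boundary ellipse fit failed")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if a < b:
        a, b = b, a
        theta += np.pi / 2.0
    return np.array([xc, yc]), float(a), float(b), float(theta)


def coregister(
    seg: ReferenceSegmentation,
    manual_rotation_deg: float | None = None,
    residual_threshold: float = 0.08,
) -> tuple[RigidTransformSpec, list[FascicleCoM]]:
    """Map a segmented reference section into the circular fiducial-aligned
    frame and return the transform plus fascicle CoMs (µm, polar).

    The rotation is automated from the detected fiducial position;
    ``manual_rotation_deg`` overrides it.  A circle-fit residual (after
    rescaling) above ``residual_threshold`` × nerve radius raises
    :class:`CoregistrationError`.
    """
    pts = np.asarray(seg.boundary_px, dtype=float)
    center, a, b, theta = _fit_boundary_ellipse(pts)
    R_um = seg.nerve_radius_um

    # transform built in +y-up coordinates: subtract center, flip the row
    # axis, rotate the fitted major axis onto +x, rescale per axis so the
    # outline becomes the circle of radius R_um, rotate back
    th_up = -theta  # EllipseModel angle is CCW in (x=col, y=row); row flip negates it
    ca, sa = np.cos(th_up), np.sin(th_up)
    R_axes = np.array([[ca, sa], [-sa, ca]])  # rotates major axis onto +x
    k_major = R_um / (a * seg.pixel_size_um)
    k_minor = R_um / (b * seg.pixel_size_um)
    lin = R_axes.T @ np.diag([k_major, k_minor]) @ R_axes * seg.pixel_size_um

    def apply_lin(p_px: np.ndarray) -> np.ndarray:
        q = (np.atleast_2d(np.asarray(p_px, float)) - center) * np.array([1.0, -1.0])
        return q @ lin.T

    circ = apply_lin(pts)
    resid = np.hypot(circ[:, 0], circ[:, 1]) - R_um
    resid_rms = float(np.sqrt(np.mean(resid**2)))
    if resid_rms > residual_threshold * R_um:
        raise CoregistrationError(
            f"boundary not circular after rescaling (RMS {resid_rms:.1f} µm)"
        )

    if manual_rotation_deg is not None:
        rot = manual_rotation_deg
    else:
        f = apply_lin(seg.fiducial_px)[0]
        rot = theta_from_xy(f[0], f[1])  # rotate fiducial back to 0° (top)

    def to_common(p_px) -> np.ndarray:
        q = apply_lin(p_px)
        r, th = polar_from_xy(q[:, 0], q[:, 1])
        th = np.mod(th - rot, 360.0)
        if seg.side == "left":
            th = np.mod(360.0 - th, 360.0)
        x = r * np.sin(np.radians(th))
        y = r * np.cos(np.radians(th))
        return np.column_stack([x, y])

    labels = _resolve_labels(seg)
    coms = []
    for key, mask in seg.masks.items():
        if key == "nerve":
            continue
        (cx, cy), *_ = fit_ellipse(mask)
        p = to_common(np.array([[cx, cy]]))[0]
        r, th = polar_from_xy(p[0], p[1])
        coms.append(
            FascicleCoM(
                x_um=float(p[0]),
                y_um=float(p[1]),
                r_um=float(r),
                theta_deg=float(th),
                label=labels[key],
                technique=seg.modality,
                nerve_id=seg.nerve_id,
                side=seg.side,
            )
        )

    spec = RigidTransformSpec(
        scale_major=k_major,
        scale_minor=k_minor,
        axis_angle_deg=float(np.degrees(th_up)),
        rotation_deg=float(rot),
        translation_um=(float(-center[0] * seg.pixel_size_um), float(center[1] * seg.pixel_size_um)),
        flip_horizontal=seg.side == "left",
        residual_rms_um=resid_rms,
    )
    return spec, coms


def _resolve_labels(seg: ReferenceSegmentation) -> dict[str, str]:
    """Resolve anatomical labels; the largest unlabeled mask is the sural
    fascicle (no tracer reaches it in histology)."""
    labels = dict(seg.mask_labels)
    unlabeled = [k for k, v in labels.items() if v == "?"]
    if unlabeled:
        largest = max(unlabeled, key=lambda k: int(seg.masks[k].sum()))
        labels[largest] = "sural"
        for k in unlabeled:
            if k != largest:
                labels[k] = f"unlabeled:{k}"
    return labels


def segmentation_from_reference(
    ref: ReferenceImages, nerve_id: str = "", n_boundary: int = 256
) -> ReferenceSegmentation:
    """Build a segmentation from rendered reference images: boundary points
    sampled from the nerve mask contour, fascicle masks passed through."""
    from skimage import measure

    contours = measure.find_contours(ref.masks["nerve"].astype(float), 0.5)
    boundary_rc = max(contours, key=len)
    step = max(1, len(boundary_rc) // n_boundary)
    pts = boundary_rc[::step][:, ::-1]  # (row, col) -> (x=col, y=row)
    masks = {k: v for k, v in ref.masks.items() if k != "nerve"}
    masks["nerve"] = ref.masks["nerve"]
    return ReferenceSegmentation(
        boundary_px=pts,
        masks=masks,
        mask_labels=dict(ref.mask_labels),
        fiducial_px=ref.fiducial_px,
        pixel_size_um=ref.pixel_size_um,
        side=ref.side,
        modality=ref.modality,
        nerve_id=nerve_id,
        nerve_radius_um=ref.nerve_radius_um,
    )


def compare_coms(coms: list[FascicleCoM] | pd.DataFrame) -> pd.DataFrame:
    """Pairwise CoM distances between techniques sharing (nerve, fascicle).

    Returns one row per (nerve, fascicle, technique pair) with the Euclidean
    distance (µm) and the radial/angular differences; unmatched entries are
    dropped with a warning column in the summary attrs.
    """
    if isinstance(coms, list):
        df = pd.DataFrame(
            [
                dict(
                    nerve_id=c.nerve_id,
                    label=c.label,
                    technique=c.technique,
                    x_um=c.x_um,
                    y_um=c.y_um,
                    r_um=c.r_um,
                    theta_deg=c.theta_deg,
                )
                for c in coms
            ]
        )
    else:
        df = coms.copy()
    rows = []
    for (nerve, label), grp in df.groupby(["nerve_id", "label"]):
        techs = sorted(grp["technique"].unique())
        for i in range(len(techs)):
            for j in range(i + 1, len(techs)):
                p = grp[grp.technique == techs[i]].iloc[0]
                q = grp[grp.technique == techs[j]].iloc[0]
                dth = (p.theta_deg - q.theta_deg + 180.0) % 360.0 - 180.0
                rows.append(
                    dict(
                        nerve_id=nerve,
                        label=label,
                        pair=f"{techs[i]}|{techs[j]}",
                        distance_um=float(np.hypot(p.x_um - q.x_um, p.y_um - q.y_um)),
                        dr_um=float(p.r_um - q.r_um),
                        dtheta_deg=float(dth),
                    )
                )
    return pd.DataFrame(rows)
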