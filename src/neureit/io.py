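"""Persistence: HDF5 recording/Jacobian containers, TIFF/PNG images,
CSV/JSON tables.

Every container carries its generator seed and enough metadata to rebuild
the ground truth — no phantom output is written without its answer key.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .forward import InjectionProtocol, JacobianMatrix
from .phantom import (
    ActivityEvent,
    DistortionSpec,
    FasciclePhantom,
    FascicleSpec,
    RawRecording,
    ReferenceImages,
)


def phantom_to_dict(ph: FasciclePhantom) -> dict:
    return dict(
        nerve_radius_um=ph.nerve_radius_um,
        side=ph.side,
        fiducial_deg=ph.fiducial_deg,
        seed=ph.seed,
        fascicles=[asdict(f) for f in ph.fascicles],
    )


def phantom_from_dict(d: dict) -> FasciclePhantom:
    return FasciclePhantom(
        nerve_radius_um=d["nerve_radius_um"],
        side=d["side"],
        fiducial_deg=d["fiducial_deg"],
        seed=d["seed"],
        fascicles=[FascicleSpec(**f) for f in d["fascicles"]],
    )


def save_recording(rec: RawRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sample_rate"] = rec.sample_rate
        f.attrs["seed"] = rec.seed
        f.attrs["stim_rate_hz"] = rec.stim_rate_hz
        f.attrs["noise_sd_v"] = rec.noise_sd_v
        f.attrs["carrier_hz"] = rec.protocol.carrier_hz
        f.attrs["current_a"] = rec.protocol.current_a
        f.attrs["n_electrodes"] = rec.protocol.n_electrodes
        f.attrs["phantom_json"] = json.dumps(phantom_to_dict(rec.phantom))
        f.attrs["event_json"] = json.dumps(asdict(rec.event))
        f.create_dataset("triggers_s", data=rec.triggers_s)
        f.create_dataset("pairs", data=np.asarray(rec.protocol.pairs))
        f.create_dataset("baseline_voltages", data=rec.baseline_voltages)
        f.create_dataset("perturbed_voltages", data=rec.perturbed_voltages)
        g = f.create_group("injections")
        for k, w in enumerate(rec.waveforms):
            g.create_dataset(f"{k:03d}", data=w, compression="gzip", compression_opts=1)


def load_recording(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        pairs = [tuple(int(v) for v in p) for p in f["pairs"][()]]
        protocol = InjectionProtocol(
            pairs=pairs,
            current_a=float(f.attrs["current_a"]),
            carrier_hz=float(f.attrs["carrier_hz"]),
            n_electrodes=int(f.attrs["n_electrodes"]),
        )
        waveforms = [
            f["injections"][k][()] for k in sorted(f["injections"].keys())
        ]
        return RawRecording(
            waveforms=waveforms,
            triggers_s=f["triggers_s"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            protocol=protocol,
            phantom=phantom_from_dict(json.loads(f.attrs["phantom_json"])),
            event=ActivityEvent(**json.loads(f.attrs["event_json"])),
            baseline_voltages=f["baseline_voltages"][()],
            perturbed_voltages=f["perturbed_voltages"][()],
            noise_sd_v=float(f.attrs["noise_sd_v"]),
            seed=int(f.attrs["seed"]),
            stim_rate_hz=float(f.attrs["stim_rate_hz"]),
        )


def save_jacobian(J: JacobianMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = J.kind
        f.create_dataset("matrix", data=J.matrix, compression="gzip", compression_opts=1)
        f.create_dataset("row_index", data=np.asarray(J.row_index))
        if J.kind == "voxel":
            f.attrs["voxel_size"] = J.voxel_size
            f.attrs["grid_shape"] = J.grid_shape
            f.create_dataset("voxel_centers", data=J.voxel_centers)
            f.create_dataset("grid_index", data=J.grid_index)
        elif J.col_elements is not None:
            f.create_dataset("col_elements", data=J.col_elements)


def load_jacobian(path) -> JacobianMatrix:
    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        kw = dict(
            matrix=f["matrix"][()],
            row_index=[tuple(int(v) for v in r) for r in f["row_index"][()]],
            kind=kind,
        )
        if kind == "voxel":
            kw.update(
                voxel_size=float(f.attrs["voxel_size"]),
                grid_shape=tuple(int(v) for v in f.attrs["grid_shape"]),
                voxel_centers=f["voxel_centers"][()],
                grid_index=f["grid_index"][()],
            )
        elif "col_elements" in f:
            kw["col_elements"] = f["col_elements"][()]
        return JacobianMatrix(**kw)


def save_reference_images(ref: ReferenceImages, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        out_dir / f"{ref.modality}.tif",
        (np.clip(ref.image, 0, 1) * 65535).astype(np.uint16),
    )
    import imageio.v3 as iio

    for key, mask in ref.masks.items():
        iio.imwrite(out_dir / f"{ref.modality}_mask_{key}.png", (mask * 255).astype(np.uint8))
    sidecar = dict(
        modality=ref.modality,
        pixel_size_um=ref.pixel_size_um,
        side=ref.side,
        seed=ref.seed,
        nerve_radius_um=ref.nerve_radius_um,
        fiducial_px=list(ref.fiducial_px),
        mask_labels=ref.mask_labels,
        distortion=asdict(ref.distortion),
        com_true_um={k: list(v) for k, v in ref.com_true_um.items()},
        com_distorted_um={k: list(v) for k, v in ref.com_distorted_um.items()},
    )
    with open(out_dir / f"{ref.modality}.json", "w") as f:
        json.dump(sidecar, f, indent=2, sort_keys=True)


def load_reference_images(out_dir, modality: str) -> ReferenceImages:
    out_dir = Path(out_dir)
    import imageio.v3 as iio

    with open(out_dir / f"{modality}.json") as f:
        meta = json.load(f)
    image = tifffile.imread(out_dir / f"{modality}.tif").astype(float) / 65535.0
    masks = {}
    for p in sorted(out_dir.glob(f"{modality}_mask_*.png")):
        key = p.stem.replace(f"{modality}_mask_", "")
        masks[key] = iio.imread(p) > 127
    return ReferenceImages(
        image=image,
        pixel_size_um=meta["pixel_size_um"],
        masks=masks,
        mask_labels=meta["mask_labels"],
        distortion=DistortionSpec(**meta["distortion"]),
        fiducial_px=tuple(meta["fiducial_px"]),
        com_true_um={k: tuple(v) for k, v in meta["com_true_um"].items()},
        com_distorted_um={k: tuple(v) for k, v in meta["com_distorted_um"].items()},
        modality=modality,
        side=meta["side"],
        nerve_radius_um=meta["nerve_radius_um"],
        seed=meta["seed"],
    )


def save_image(img, path_tif, path_png=None) -> None:
    """Write a PixelImage as float32 TIFF and optionally a rainbow PNG
    preview highlighting the top 50% of the normalized range."""
    tifffile.imwrite(path_tif, img.values.astype(np.float32))
    if path_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vals = np.where(img.mask, img.values, np.nan)
        vmax = np.nanmax(vals)
        fig, ax = plt.subplots(figsize=(4, 4))
        shown = np.where(vals >= 0.5 * vmax, vals, np.nan)
        ax.imshow(np.where(img.mask, 0.15, np.nan), cmap="gray", vmin=0, vmax=1, origin="lower")
        ax.imshow(shown, cmap="rainbow", origin="lower")
        ax.set_axis_off()
        fig.savefig(path_png, dpi=120, bbox_inches="tight")
        plt.close(fig)
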