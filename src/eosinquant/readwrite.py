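"""File I/O: TIFF rasters, wavelength metadata, CSV reports, YAML configs.

Conventions used throughout: row-major images with the origin at the top
left; masks are 0/255 uint8 in files and boolean in memory; multi-page
TIFF is the sole raster interchange format, with the emission wavelength
of each lambda-stack page recorded in its page description (JSON).  Peak
maps are written as 32-bit float TIFF in nm with NaN marking invalid
pixels, plus an 8-bit pseudo-colour rendering.
"""

from __future__ import annotations

import csv
import json
import re
import xml.etree.ElementTree as ElementTree
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .phantom import Phantom, PhantomSpec
from .quantify import ChannelPair, QuantResult
from .spectral import LambdaStack, PeakMap, SpectrumProfile

__all__ = [
    "read_stack",
    "write_stack",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_channel_pair",
    "write_phantom",
    "write_peak_map",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_report",
    "read_report",
    "parse_wavelength_spec",
    "load_phantom_spec",
    "save_phantom_spec",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "file",
    "tissue_threshold",
    "blood_threshold",
    "tissue_area_px",
    "blood_area_px",
    "tissue_area_um2",
    "blood_area_um2",
    "blood_percent",
]


# ---------------------------------------------------------------------------
# wavelength specifications


def parse_wavelength_spec(spec: str, n_planes: int) -> np.ndarray:
    """Parse an explicit wavelength specification.

    Accepted forms: ``"480:10"`` (start:step, one value per plane),
    ``"480:10:22"`` (start:step:count) or a comma list ``"480,490,..."``.
    """
    spec = spec.strip()
    if "," in spec:
        values = np.array([float(tok) for tok in spec.split(",") if tok.strip()])
    elif re.fullmatch(r"[-\d.]+:[-\d.]+(:\d+)?", spec):
        parts = spec.split(":")
        start, step = float(parts[0]), float(parts[1])
        count = int(parts[2]) if len(parts) == 3 else n_planes
        values = start + step * np.arange(count)
    else:
        raise ValueError(
            f"cannot parse wavelength specification {spec!r}; "
            "use start:step, start:step:count, or a comma-separated list"
        )
    if values.size != n_planes:
        raise ValueError(
            f"wavelength count mismatch: {values.size} wavelengths for {n_planes} planes"
        )
    return values


def _wavelengths_from_pages(tif: tifffile.TiffFile) -> np.ndarray | None:
    values = []
    for page in tif.pages:
        desc = page.description
        if not desc:
            return None
        try:
            meta = json.loads(desc)
            values.append(float(meta["wavelength_nm"]))
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            return None
    return np.array(values) if values else None


def _wavelengths_from_ome(tif: tifffile.TiffFile, n_planes: int) -> np.ndarray | None:
    if not tif.is_ome or not tif.ome_metadata:
        return None
    try:
        root = ElementTree.fromstring(tif.ome_metadata)
    except ElementTree.ParseError:
        return None
    values = [
        float(ch.attrib["EmissionWavelength"])
        for ch in root.iter()
        if ch.tag.endswith("Channel") and "EmissionWavelength" in ch.attrib
    ]
    if len(values) == n_planes:
        return np.array(values)
    return None


def read_stack(
    path: str | Path,
    wavelengths: str | None = None,
    pixel_size_um: float | None = None,
) -> LambdaStack:
    """Read a lambda stack from a multi-page TIFF or OME-TIFF.

    Wavelengths are taken from embedded metadata (per-page JSON
    descriptions, or OME channel emission wavelengths) when present;
    otherwise an explicit ``wavelengths`` specification is required —
    the reader never guesses.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"unreadable stack: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.series) > 1:  # one series per plane (per-page descriptions)
            planes = np.stack([s.asarray() for s in tif.series])
        else:
            planes = tif.series[0].asarray()
            if planes.ndim == 2:
                planes = planes[None]
        if planes.ndim != 3:
            raise ValueError(f"{path}: expected a stack of 2-D planes, got shape {planes.shape}")
        embedded = _wavelengths_from_pages(tif)
        if embedded is None:
            embedded = _wavelengths_from_ome(tif, planes.shape[0])
    if wavelengths is not None:
        wl = parse_wavelength_spec(wavelengths, planes.shape[0])
    elif embedded is not None:
        if embedded.size != planes.shape[0]:
            raise ValueError(
                f"wavelength count mismatch: {embedded.size} wavelengths "
                f"for {planes.shape[0]} planes"
            )
        wl = embedded
    else:
        raise ValueError(
            f"{path} carries no wavelength metadata; pass an explicit "
            "wavelength specification (start:step or a comma list)"
        )
    return LambdaStack(wavelengths=wl, planes=planes.astype(np.float64), pixel_size_um=pixel_size_um)


def write_stack(stack: LambdaStack, path: str | Path) -> Path:
    """Write a lambda stack as multi-page TIFF, one page per wavelength.

    Each page's description records its band centre, so the file can be
    re-read without an external wavelength specification.  Planes are
    stored as float64, making write/read round trips bit-exact.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tif:
        for wl, plane in zip(stack.wavelengths, stack.planes):
            tif.write(
                plane,
                description=json.dumps({"wavelength_nm": float(wl)}),
                contiguous=False,
            )
    return path


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"unreadable image: {path}")
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {img.shape}")
    return img


def write_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image))
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as 8-bit TIFF with values 0/255."""
    mask = np.asarray(mask, dtype=bool)
    return write_image((mask * np.uint8(255)), path)


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 0


def read_channel_pair(
    fitc_path: str | Path,
    tritc_path: str | Path,
    pixel_size_um: float | None = None,
) -> ChannelPair:
    """Read co-registered FITC and TRITC single-channel TIFFs."""
    fitc = read_image(fitc_path).astype(np.float64)
    tritc = read_image(tritc_path).astype(np.float64)
    return ChannelPair(fitc=fitc, tritc=tritc, pixel_size_um=pixel_size_um)


def write_phantom(phantom: Phantom, outdir: str | Path) -> dict[str, Path]:
    """Write a rendered phantom: stack, channels, masks and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": write_stack(phantom.stack, outdir / "stack.tif"),
        "fitc": write_image(phantom.channels.fitc, outdir / "fitc.tif"),
        "tritc": write_image(phantom.channels.tritc, outdir / "tritc.tif"),
        "tissue_mask": write_mask(phantom.tissue_mask, outdir / "tissue_mask.tif"),
        "blood_mask": write_mask(phantom.blood_mask, outdir / "blood_mask.tif"),
    }
    truth = outdir / "truth.json"
    truth.write_text(
        json.dumps(
            {
                "true_blood_percent": phantom.true_blood_percent,
                "tissue_area_px": int(phantom.tissue_mask.sum()),
                "blood_area_px": int(phantom.blood_mask.sum()),
                "pixel_size_um": phantom.spec.pixel_size_um,
            },
            indent=2,
        )
    )
    paths["truth"] = truth
    return paths


def write_peak_map(peakmap: PeakMap, path: str | Path, colour_path: str | Path | None = None) -> Path:
    """Write a peak map as 32-bit float TIFF (nm, NaN = invalid).

    Optionally also writes an 8-bit pseudo-colour rendering (viridis over
    the stack's wavelength range, black where invalid).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, peakmap.peak_wavelength.astype(np.float32))
    if colour_path is not None:
        from matplotlib import colormaps

        lo, hi = peakmap.wavelength_range
        norm = np.clip((peakmap.peak_wavelength - lo) / max(hi - lo, 1e-12), 0, 1)
        rgba = colormaps["viridis"](np.nan_to_num(norm))
        rgb = (rgba[..., :3] * 255).astype(np.uint8)
        rgb[~peakmap.valid_mask] = 0
        tifffile.imwrite(Path(colour_path), rgb, photometric="rgb")
    return path


def write_spectrum_csv(profile: SpectrumProfile, path: str | Path) -> Path:
    """Write an ROI spectrum as two-column CSV (wavelength_nm, mean_intensity)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", "mean_intensity"])
        for wl, mi in zip(profile.wavelengths, profile.mean_intensity):
            writer.writerow([f"{wl:g}", repr(float(mi))])
    return path


def read_spectrum_csv(path: str | Path, n_pixels: int = 1) -> SpectrumProfile:
    import pandas as pd

    frame = pd.read_csv(path, float_precision="round_trip")
    return SpectrumProfile(
        wavelengths=frame["wavelength_nm"].to_numpy(dtype=float),
        mean_intensity=frame["mean_intensity"].to_numpy(dtype=float),
        n_pixels=n_pixels,
    )


def _format_row(name: str, result: QuantResult) -> dict[str, str]:
    def um2(value: float | None) -> str:
        return "" if value is None else f"{value:.2f}"

    return {
        "file": name,
        "tissue_threshold": str(result.tissue_threshold),
        "blood_threshold": "" if result.blood_threshold is None else str(result.blood_threshold),
        "tissue_area_px": str(result.tissue_area_px),
        "blood_area_px": str(result.blood_area_px),
        "tissue_area_um2": um2(result.tissue_area_um2),
        "blood_area_um2": um2(result.blood_area_um2),
        "blood_percent": f"{result.blood_percent:.2f}",
    }


def write_report(results: list[tuple[str, QuantResult]], path: str | Path) -> Path:
    """Write quantification results as CSV, one row per image.

    Areas are integers (px) / two-decimal um^2; percentages two decimals.
    An empty result list is an error and no file is created.
    """
    if not results:
        raise ValueError("no results to report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS)
        writer.writeheader()
        for name, result in results:
            writer.writerow(_format_row(name, result))
    return path


def read_report(path: str | Path):
    """Read a results CSV back into a DataFrame."""
    import pandas as pd

    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# phantom spec configs


def _plain(obj):
    """Recursively convert tuples and numpy scalars for YAML round trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def save_phantom_spec(spec: PhantomSpec, path: str | Path) -> Path:
    """Serialise a PhantomSpec to YAML (keys mirror the field names)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        yaml.safe_dump(_plain(spec.to_dict()), fh, sort_keys=False)
    return path


def load_phantom_spec(path: str | Path, seed: int | None = None) -> PhantomSpec:
    """Load a PhantomSpec from YAML; ``seed`` overrides the file's seed."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of PhantomSpec fields")
    if seed is not None:
        data["seed"] = seed
    return PhantomSpec.from_dict(data)
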