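"""File formats, run configuration and logging.

Conventions used throughout the package: coordinates in µm, right-handed,
with the stimulus centre at the origin; image arrays indexed (row, col) with
row 0 at top; half-open sample intervals; CSV with comma separator, UTF-8,
header row and '.' decimal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidArgumentError, ParseError
from .morphology import Skeleton

log = logging.getLogger("dendrint")


def configure_logging(verbosity: int = 0) -> None:
    """Route package logs to stderr; verbosity 0=warning, 1=info, 2=debug."""
    level = [logging.WARNING, logging.INFO, logging.DEBUG][min(verbosity, 2)]
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


# ---------------------------------------------------------------------------
# SWC skeletons
# ---------------------------------------------------------------------------

def read_swc(path, ipl_axis=None) -> Skeleton:
    """Read an SWC skeleton (1-based ids, parent -1 for the root).

    The SWC structure-type column is accepted but only the tree topology,
    positions and radii are used; the single root is taken as the soma.
    """
    ids, parents, xyz, radius = [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ParseError(f"expected 7 columns, got {len(parts)}", line=ln)
            try:
                i = int(parts[0]); p = int(parts[6])
                x, y, z, r = (float(v) for v in parts[2:6])
            except ValueError as err:
                raise ParseError(str(err), line=ln) from err
            ids.append(i); parents.append(p)
            xyz.append((x, y, z)); radius.append(r)
    if not ids:
        raise ParseError("no SWC records found")
    try:
        return Skeleton(ids, parents, xyz, radius, ipl_axis=ipl_axis)
    except InvalidArgumentError as err:
        raise ParseError(f"invalid skeleton: {err}") from err


def write_swc(skeleton: Skeleton, path) -> None:
    """Write a skeleton as SWC, preserving positions/radii at full precision."""
    root = skeleton.root_index
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(skeleton.n_nodes):
            stype = 1 if k == root else 3
            x, y, z = (repr(float(v)) for v in skeleton.xyz[k])
            fh.write(f"{int(skeleton.ids[k])} {stype} {x} {y} {z} "
                     f"{float(skeleton.radius[k])!r} {int(skeleton.parents[k])}\n")


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """Time-lapsed fluorescence movie: ``data`` is T×H×W (a.u.)."""

    data: np.ndarray
    frame_rate: float = 31.25   # Hz
    pixel_size: float = 1.0     # µm

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise InvalidArgumentError("stack must be T×H×W with T >= 2")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("stack contains non-finite values")

    @property
    def shape(self):
        return self.data.shape


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page TIFF (``.tif``) or NumPy archive (``.npz``),
    with a JSON metadata sidecar next to TIFFs."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, stack.data.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"frame_rate": stack.frame_rate, "pixel_size": stack.pixel_size}))
    elif path.suffix == ".npz":
        np.savez_compressed(path, data=stack.data,
                            frame_rate=stack.frame_rate, pixel_size=stack.pixel_size)
    else:
        raise InvalidArgumentError(f"unsupported stack format: {path.suffix}")


def read_stack(path) -> ImageStack:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path))
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        else:
            log.warning("no metadata sidecar for %s; assuming 31.25 Hz, 1 µm px", path)
            meta = {"frame_rate": 31.25, "pixel_size": 1.0}
        return ImageStack(data, float(meta["frame_rate"]), float(meta["pixel_size"]))
    if path.suffix == ".npz":
        with np.load(path) as z:
            return ImageStack(z["data"], float(z["frame_rate"]), float(z["pixel_size"]))
    raise InvalidArgumentError(f"unsupported stack format: {path.suffix}")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters of an end-to-end pipeline run.

    Unknown keys are rejected on load so that typos cannot silently fall back
    to defaults.
    """

    seed: int = 0
    out_dir: str = "dendrint_out"
    preset: str = "toff-alpha"          # synthetic preset
    noise_sigma: float = 0.2            # movie noise, a.u.
    stimulus_duration: float = 300.0    # s of dense noise
    n_lags: int = 5                     # RF lags (design at stimulus refresh)
    contour_thresholds: tuple = (0.60, 0.65, 0.70)
    upsample_factor: int = 10
    rho_detrend: bool = False
    chirp_reps: int = 5
    chirp_snr: float = 5.0
    verbosity: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.contour_thresholds, list):
            cfg.contour_thresholds = tuple(cfg.contour_thresholds)
        return cfg

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contour_thresholds"] = list(self.contour_thresholds)
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def provenance(config: RunConfig | None = None, seed: int | None = None) -> dict:
    """Provenance block written next to every pipeline output."""
    import hashlib

    from . import __version__

    block = {"dendrint_version": __version__,
             "numpy_version": np.__version__}
    if config is not None:
        payload = json.dumps(config.to_dict(), sort_keys=True).encode()
        block["config_sha1"] = hashlib.sha1(payload).hexdigest()
        block["seed"] = config.seed
    if seed is not None:
        block["seed"] = seed
    return block
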