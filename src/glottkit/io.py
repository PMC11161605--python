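"""File I/O: frame stacks (TIFF / PNG directories), WAV signals, CSV.

Frame stacks travel as multi-page TIFF or a directory of numbered PNG
frames, either way with a JSON sidecar holding the frame rate and
labels.  Audio and EGG use plain WAV (float32); glottovibrograms and
closed-quotient profiles serialize to CSV with rows = antero-posterior
positions.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy.io import wavfile

from .kinematics import CQProfile, Glottovibrogram
from .preprocess import HSVSequence
from .signals import VoiceSignal

__all__ = [
    "save_hsv",
    "load_hsv",
    "save_wav",
    "load_wav",
    "save_gvg_csv",
    "load_gvg_csv",
    "save_cq_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_hsv(seq: HSVSequence, path: str | Path) -> None:
    """Write a frame stack as multi-page TIFF (or PNG dir) + JSON sidecar.

    A path ending in ``.tif``/``.tiff`` writes one multi-page TIFF;
    otherwise ``path`` is created as a directory of ``frame_%06d.png``.
    Intensities are rescaled to uint16 full range; the scale is stored
    in the sidecar.
    """
    path = Path(path)
    lo, hi = float(seq.frames.min()), float(seq.frames.max())
    scale = (hi - lo) or 1.0
    data = ((seq.frames - lo) / scale * 65535).astype(np.uint16)
    meta = {"fps": seq.fps, "intensity_offset": lo, "intensity_scale": scale,
            "metadata": seq.metadata}
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data, photometric="minisblack")
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(data):
            iio.imwrite(path / f"frame_{i:06d}.png", frame)
        (path / "sequence.json").write_text(json.dumps(meta, indent=1))


def load_hsv(path: str | Path, fps: float | None = None) -> HSVSequence:
    """Read a frame stack written by :func:`save_hsv` (or any TIFF/PNGs)."""
    path = Path(path)
    meta: dict = {}
    if path.is_dir():
        sidecar = path / "sequence.json"
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        data = np.stack([iio.imread(f) for f in files]).astype(float)
    else:
        sidecar = _sidecar(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        data = tifffile.imread(path).astype(float)
        if data.ndim == 2:
            data = data[None]
    if "intensity_scale" in meta:
        data = data / 65535.0 * meta["intensity_scale"] + meta["intensity_offset"]
    fps = fps if fps is not None else meta.get("fps")
    if fps is None:
        raise ValueError("fps not in sidecar; pass fps= explicitly")
    return HSVSequence(data, float(fps), meta.get("metadata", {}))


def save_wav(sig: VoiceSignal, path: str | Path) -> None:
    """Write a signal as float32 WAV at its own sampling rate."""
    wavfile.write(str(path), int(round(sig.fs)),
                  sig.samples.astype(np.float32))


def load_wav(path: str | Path, kind: str = "audio") -> VoiceSignal:
    """Read a WAV file; integer PCM is rescaled to [-1, 1]."""
    fs, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return VoiceSignal(data.astype(float), float(fs), kind=kind)


def save_gvg_csv(gvg: Glottovibrogram, path: str | Path) -> None:
    """GVG to CSV: first column ap position, remaining columns frames."""
    out = np.column_stack([gvg.ap_positions, gvg.width])
    header = "ap_position," + ",".join(
        f"frame_{i}" for i in range(gvg.width.shape[1]))
    np.savetxt(path, out, delimiter=",", header=header, comments="")
    _sidecar(Path(path)).write_text(json.dumps({"fps": gvg.fps}))


def load_gvg_csv(path: str | Path, fps: float | None = None) -> Glottovibrogram:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if fps is None:
        sidecar = _sidecar(Path(path))
        if not sidecar.exists():
            raise ValueError("fps not in sidecar; pass fps= explicitly")
        fps = json.loads(sidecar.read_text())["fps"]
    return Glottovibrogram(data[:, 1:], float(fps), data[:, 0])


def save_cq_csv(profile: CQProfile, path: str | Path) -> None:
    """CQ profile to CSV: ap position index and closed quotient."""
    n = profile.cq.size
    ap = np.linspace(0, 1, n) if n > 1 else np.zeros(1)
    np.savetxt(path, np.column_stack([ap, profile.cq]), delimiter=",",
               header="ap_position,cq", comments="")
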