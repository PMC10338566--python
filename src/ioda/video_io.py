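"""Reading and writing video frame stacks.

The default container is a multi-page TIFF (lossless uint8, one page per
frame), which every scientific imaging stack can read and which keeps the
pipeline free of codec dependencies.  MP4/AVI writing is attempted through
whatever ffmpeg-capable imageio plugin is present and fails with a clear
error when none is — anonymization must never silently fall back to an
unencoded path.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v2 as imageio
import numpy as np

_TIFF_SUFFIXES = {".tif", ".tiff"}
_FFMPEG_SUFFIXES = {".mp4", ".avi", ".mov", ".mkv"}


class CodecUnavailableError(RuntimeError):
    """No backend can encode/decode the requested container."""


def write_video(path: str | Path, frames: np.ndarray, fps: float) -> Path:
    """Write frames (N,H,W,3), float in [0,1] or uint8, to ``path``.

    Container is chosen by suffix; ``.tif``/``.tiff`` is the lossless
    default.  ``fps`` is carried by the caller's metadata (annotation
    track / video record) for TIFF, and passed to the encoder otherwise.
    """
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError(f"expected frames of shape (N,H,W,3), got {frames.shape}")
    if frames.dtype != np.uint8:
        frames = (np.clip(frames, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        imageio.mimwrite(path, list(frames))
        return path
    if suffix in _FFMPEG_SUFFIXES:
        try:
            with imageio.get_writer(path, format="FFMPEG", fps=fps) as writer:
                for frame in frames:
                    writer.append_data(frame)
        except Exception as exc:  # imageio raises various plugin errors
            path.unlink(missing_ok=True)  # never leave a partial output behind
            raise CodecUnavailableError(
                f"no encoder available for container {suffix!r} ({path.name}); "
                "install an ffmpeg backend or use the .tiff container"
            ) from exc
        return path
    raise ValueError(f"unsupported video container {suffix!r}")


def read_video(path: str | Path) -> np.ndarray:
    """Read a frame stack back as float64 (N,H,W,3) in [0,1]."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        frames = np.asarray(imageio.mimread(path, memtest=False))
    elif suffix in _FFMPEG_SUFFIXES:
        try:
            reader = imageio.get_reader(path, format="FFMPEG")
        except Exception as exc:
            raise CodecUnavailableError(
                f"no decoder available for container {suffix!r} ({path.name})"
            ) from exc
        with reader:
            frames = np.asarray([im for im in reader])
    else:
        raise ValueError(f"unsupported video container {suffix!r}")
    if frames.ndim == 3:  # single frame
        frames = frames[None]
    return frames.astype(np.float64) / 255.0
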