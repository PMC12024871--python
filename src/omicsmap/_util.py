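"""Small shared helpers: angle canonicalization and atomic file writes."""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager

import numpy as np

TWO_PI = 2.0 * np.pi


def canonical_angle(theta):
    """Map angles into [0, 2*pi). Accepts scalars or arrays."""
    out = np.mod(theta, TWO_PI)
    # mod can return 2*pi for tiny negative inputs due to rounding
    out = np.where(out >= TWO_PI, out - TWO_PI, out)
    if np.isscalar(theta):
        return float(out)
    return out


@contextmanager
def atomic_write(path, mode="w"):
    """Write to a temp file in the target directory, then rename into place.

    Guarantees the destination is never left half-written.
    """
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-omicsmap-")
    try:
        with os.fdopen(fd, mode, newline="") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def format_float(x: float) -> str:
    """Shortest representation that round-trips through float()."""
    return repr(float(x))
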