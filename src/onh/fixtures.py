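"""Packaged per-animal study tables.

Two CSV fixtures transcribed from the study's printed per-animal tables:

* ``table1_iop`` -- demographics and intraocular pressure profile of each
  eye: baseline IOP (mean +/- SD), number of microbead injections, weeks
  from first injection to IOP elevation, and the months-2-7 mean and
  maximum IOP (each +/- SD).  One row per eye (32 rows).
* ``table2_morphometry`` -- mean minimum rim width and lamina cribrosa
  depth (each +/- SD) of every eye at baseline and at month 7.  One row per
  (animal, eye, timepoint) (64 rows).

The files are checksum-pinned; :func:`verify_fixtures` fails if either is
edited.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .errors import FixtureLookupError, FormatError

__all__ = ["load_fixture", "fixture_names", "verify_fixtures", "FIXTURE_SHA256"]

_FIXTURE_FILES = {
    "table1_iop": "table1_iop.csv",
    "table2_morphometry": "table2_morphometry.csv",
}

# sha256 of the packaged CSV bytes; pinned so silent edits fail loudly
FIXTURE_SHA256 = {
    "table1_iop": "6991f5a6f9c3903bad300edf9c60d033005271f3b820ca11d4f524b7449c108c",
    "table2_morphometry": "ba012fb0835406e28d1d2deac2257f48c20516b5b875ddb783865fb3c28490fc",
}


def fixture_names() -> tuple[str, ...]:
    return tuple(sorted(_FIXTURE_FILES))


def _fixture_bytes(name: str) -> bytes:
    try:
        filename = _FIXTURE_FILES[name]
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    return (resources.files("onh.data") / filename).read_bytes()


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged per-animal table as a DataFrame."""
    import io as _io

    return pd.read_csv(_io.BytesIO(_fixture_bytes(name)))


def verify_fixtures() -> None:
    """Raise FormatError if any packaged fixture does not match its checksum."""
    for name, expected in FIXTURE_SHA256.items():
        actual = hashlib.sha256(_fixture_bytes(name)).hexdigest()
        if actual != expected:
            raise FormatError(
                f"fixture {name!r} checksum mismatch: expected {expected}, "
                f"got {actual}"
            )
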