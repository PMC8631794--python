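"""Named model-cell parameter sets.

All bundled parameter files are synthetic stand-ins: they were calibrated
within this package so that each named cell class reproduces the published
qualitative phenotype (and, where attainable, the published per-channel
current and conductance magnitudes) of that class; they are not transcribed
from any deposited parameter set.  Files carry a ``synthetic_`` prefix to
make this explicit.

Available names: nonadapting, adapting_firing, adapting_to_silent, typeA,
typeB.
"""

from __future__ import annotations

from importlib import resources

from ..io import read_params
from ..model_core import ModelParameters

__all__ = ["available_fixtures", "load_fixture"]


def _fixture_dir():
    return resources.files(__package__)


def available_fixtures() -> list[str]:
    out = []
    for entry in _fixture_dir().iterdir():
        name = entry.name
        if name.startswith("synthetic_") and name.endswith(".params"):
            out.append(name[len("synthetic_"):-len(".params")])
    return sorted(out)


def load_fixture(name: str) -> ModelParameters:
    """Load a named synthetic parameter set (e.g. ``"nonadapting"``)."""
    path = _fixture_dir() / f"synthetic_{name}.params"
    if not path.is_file():
        raise KeyError(f"no fixture named {name!r}; available: {available_fixtures()}")
    return read_params(path)
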