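"""Model parameters: the 36 named rate and saturation constants of one patient.

The model describes the interaction of a growing tumor ``T`` with natural
killer cells ``N``, CD8+ T cells ``L``, CD4+ T cells ``Y``, circulating
lymphocytes ``C``, the IL-2 cytokine concentration ``I`` and, under
chemotherapy, the drug concentration ``M``.  Two reference parameter sets
("patient1", "patient2") ship with the package as YAML fixtures.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "ParameterSet",
    "PARAM_FIELDS",
    "load_parameters",
    "patient1",
    "patient2",
]

#: Names of the numeric model constants, in conventional order.
PARAM_FIELDS = (
    "a", "a1", "b", "c", "c1", "d", "e", "f", "g", "g_i", "h", "j", "k",
    "K_T", "K_N", "K_L", "K_C", "l", "m", "p", "p_i", "q", "r1", "r2",
    "s", "u", "alpha", "alpha1", "alpha2", "beta", "beta1", "beta2",
    "gamma", "mu1", "mu_i", "delta2",
)


@dataclass(frozen=True)
class ParameterSet:
    """Rate and saturation constants of the tumor-immune model for one patient.

    All constants are strictly positive.  Units follow the model convention:
    first-order rates in 1/day, bilinear interaction rates in 1/cell/day,
    sources in cell/day, saturation constants in cells or cell^2, and the
    exponents ``l``, ``s`` dimensionless.  ``d`` is the saturation level of
    the CD8+T fractional tumor kill and ``l`` its exponent; both must be
    positive for the lysis term to be well defined.
    """

    a: float        # tumor growth rate (1/day)
    a1: float       # half-saturation of cytokine-mediated tumor kill (cells)
    b: float        # reciprocal tumor carrying capacity (1/cell)
    c: float        # NK tumor kill rate (1/cell/day)
    c1: float       # max cytokine-mediated tumor kill (cell/day)
    d: float        # saturation level of CD8+T fractional kill (1/day)
    e: float        # lymphocyte -> NK conversion fraction (1/day)
    f: float        # NK death rate (1/day)
    g: float        # max NK recruitment by tumor (1/day)
    g_i: float      # steepness of CD8+T recruitment by cytokine (cell^2)
    h: float        # steepness of NK recruitment (cell^2)
    j: float        # max CD8+T recruitment rate (1/day)
    k: float        # steepness of CD8+T recruitment (cell^2)
    K_T: float      # chemo fractional tumor kill (1/day)
    K_N: float      # chemo fractional NK kill (1/day)
    K_L: float      # chemo fractional CD8+T kill (1/day)
    K_C: float      # chemo fractional lymphocyte kill (1/day)
    l: float        # lysis exponent (dimensionless)
    m: float        # CD8+T death rate (1/day)
    p: float        # NK inactivation by tumor (1/cell/day)
    p_i: float      # max CD8+T recruitment by cytokine (1/day)
    q: float        # CD8+T inactivation by tumor (1/cell/day)
    r1: float       # CD8+T stimulation by NK-lysed debris (1/cell/day)
    r2: float       # CD8+T activation from lymphocytes (1/cell/day)
    s: float        # lysis steepness (dimensionless)
    u: float        # NK regulation of CD8+T (1/cell^2/day)
    alpha: float    # lymphocyte source (cell/day)
    alpha1: float   # half-saturation of CD4+T production (cells)
    alpha2: float   # half-saturation of cytokine production (cells)
    beta: float     # lymphocyte death rate (1/day)
    beta1: float    # max CD4+T production rate (cell/day)
    beta2: float    # max cytokine production rate (1/cell/day)
    gamma: float    # chemo drug decay rate (1/day)
    mu1: float      # CD4+T death rate (1/day)
    mu_i: float     # cytokine decay rate (1/day)
    delta2: float   # CD4+T loss from tumor interaction (1/cell/day)
    label: str = "custom"

    def __post_init__(self) -> None:
        for name in PARAM_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, (int, float)):
                raise TypeError(f"parameter {name!r} must be numeric, got {value!r}")
            if not value > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")
            object.__setattr__(self, name, float(value))

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given constants replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        out = {name: getattr(self, name) for name in PARAM_FIELDS}
        out["label"] = self.label
        return out

    @classmethod
    def from_dict(cls, mapping: dict) -> "ParameterSet":
        data = dict(mapping)
        label = data.pop("label", "custom")
        missing = set(PARAM_FIELDS) - set(data)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")
        extra = set(data) - set(PARAM_FIELDS)
        if extra:
            raise KeyError(f"unknown parameters: {sorted(extra)}")
        return cls(label=label, **data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))


def load_parameters(source: Union[str, Path, dict]) -> ParameterSet:
    """Load a :class:`ParameterSet` from a YAML/JSON file path or a mapping.

    The file holds a flat ``name: value`` mapping using the ASCII constant
    names (``alpha1``, ``beta2``, ``mu_i``, ``delta2``, ...) plus an optional
    ``label``.
    """
    if isinstance(source, dict):
        return ParameterSet.from_dict(source)
    data = yaml.safe_load(Path(source).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{source}: expected a mapping of parameter names to values")
    return ParameterSet.from_dict(data)


def _bundled(name: str) -> ParameterSet:
    text = resources.files("tumor_immune").joinpath(f"data/{name}.yaml").read_text()
    return ParameterSet.from_dict(yaml.safe_load(text))


def patient1() -> ParameterSet:
    """Parameter set of the first reference patient."""
    return _bundled("patient1")


def patient2() -> ParameterSet:
    """Parameter set of the second reference patient."""
    return _bundled("patient2")
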