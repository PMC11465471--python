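"""Pair-class coefficient tables for the modified GB electrostatics.

Every unordered pair of topology classes (solute s, cation c, anion a)
carries two coefficients: ``gamma(a,b)``, the exponent coefficient of the
smoothing function (canonical GB has gamma = 4), and ``eps_in(a,b)``, the
effective internal dielectric for that pair. The solute–solute entry is
pinned to the canonical (gamma=4, eps_in=1) so a pure solute reduces
exactly to the canonical Still model.

Preset files use AMBER-style key aliases: ``gi_coef_1_*`` holds K_GB with
gamma = 4·K_GB, and ``intdiel_ion_1_*`` holds K_eps taken as eps_in
directly. Suffixes map pair slots: ``_p`` (s,c), ``_n`` (s,a), ``_pp``
(c,c), ``_pn`` (a,c), ``_nn`` (a,a).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import EPS_OUT_DEFAULT
from .system import ANION, CATION, SOLUTE, TOPO_CLASSES, _CLASS_CODE

# alias suffix -> (class_a, class_b)
ALIAS_SLOTS = {
    "p": (SOLUTE, CATION),
    "n": (SOLUTE, ANION),
    "pp": (CATION, CATION),
    "pn": (ANION, CATION),
    "nn": (ANION, ANION),
}

#: Range of K_GB alias values explored during parameterization.
K_GB_RANGE = (0.0, 2.0)
#: Range of K_eps alias values explored during parameterization.
K_EPS_RANGE = (1.0, 78.5)


class ParameterError(ValueError):
    """Raised for invalid pair-class coefficients."""


def _canon(cls) -> int:
    if isinstance(cls, str):
        try:
            return _CLASS_CODE[cls]
        except KeyError:
            raise ParameterError(f"unknown topology class {cls!r}") from None
    cls = int(cls)
    if cls not in (SOLUTE, CATION, ANION):
        raise ParameterError(f"unknown topology class code {cls}")
    return cls


@dataclass
class PairClassTable:
    """Symmetric (3x3) tables of gamma and eps_in, plus global eps_out."""

    gamma: np.ndarray = field(
        default_factory=lambda: np.full((3, 3), 4.0))
    eps_in: np.ndarray = field(
        default_factory=lambda: np.ones((3, 3)))
    eps_out: float = EPS_OUT_DEFAULT
    name: str = "custom"

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.eps_in = np.asarray(self.eps_in, dtype=float)
        # solute-solute is always canonical GB
        self.gamma[SOLUTE, SOLUTE] = 4.0
        self.eps_in[SOLUTE, SOLUTE] = 1.0
        if not np.allclose(self.gamma, self.gamma.T):
            raise ParameterError("gamma table is not symmetric")
        if not np.allclose(self.eps_in, self.eps_in.T):
            raise ParameterError("eps_in table is not symmetric")
        if np.any(self.gamma < 0):
            raise ParameterError("gamma must be >= 0")
        if np.any(self.eps_in < 1.0):
            raise ParameterError("eps_in must be >= 1")
        if np.any(self.eps_in > self.eps_out):
            raise ParameterError("eps_in must not exceed eps_out")

    def set_pair(self, class_a, class_b, *, gamma: float | None = None,
                 eps_in: float | None = None) -> None:
        ia, ib = _canon(class_a), _canon(class_b)
        if (ia, ib) == (SOLUTE, SOLUTE) and (
                (gamma is not None and gamma != 4.0)
                or (eps_in is not None and eps_in != 1.0)):
            raise ParameterError("the solute-solute entry is pinned to "
                                 "gamma=4, eps_in=1")
        if gamma is not None:
            self.gamma[ia, ib] = self.gamma[ib, ia] = float(gamma)
        if eps_in is not None:
            self.eps_in[ia, ib] = self.eps_in[ib, ia] = float(eps_in)
        _ = PairClassTable(self.gamma, self.eps_in, self.eps_out, self.name)

    def lookup(self, class_a, class_b) -> tuple[float, float]:
        """Return ``(gamma, eps_in)`` for an (unordered) class pair."""
        ia, ib = _canon(class_a), _canon(class_b)
        return float(self.gamma[ia, ib]), float(self.eps_in[ia, ib])

    def as_dict(self) -> dict:
        out = {"eps_out": self.eps_out, "name": self.name}
        for suffix, (ia, ib) in ALIAS_SLOTS.items():
            out[f"gi_coef_1_{suffix}"] = self.gamma[ia, ib] / 4.0
            out[f"intdiel_ion_1_{suffix}"] = self.eps_in[ia, ib]
        return out


def pair_class_lookup(table: PairClassTable, class_a, class_b):
    """Functional form of :meth:`PairClassTable.lookup`."""
    return table.lookup(class_a, class_b)


def table_from_aliases(aliases: dict, *, eps_out: float = EPS_OUT_DEFAULT,
                       name: str = "custom") -> PairClassTable:
    """Build a table from AMBER-style ``gi_coef_1_*``/``intdiel_ion_1_*`` keys."""
    gamma = np.full((3, 3), 4.0)
    eps_in = np.ones((3, 3))
    for key, value in aliases.items():
        key = key.strip().lower()
        if key in ("extdiel", "eps_out"):
            eps_out = float(value)
            continue
        for prefix, target, scale in (
                ("gi_coef_1_", gamma, 4.0), ("intdiel_ion_1_", eps_in, 1.0)):
            if key.startswith(prefix):
                suffix = key[len(prefix):]
                if suffix not in ALIAS_SLOTS:
                    raise ParameterError(f"unknown pair slot in key {key!r}")
                ia, ib = ALIAS_SLOTS[suffix]
                target[ia, ib] = target[ib, ia] = scale * float(value)
                break
        else:
            raise ParameterError(f"unrecognized preset key {key!r}")
    return PairClassTable(gamma, eps_in, eps_out, name)


def read_preset_file(path) -> PairClassTable:
    """Read a flat ``key value`` preset file (``#`` starts a comment)."""
    aliases = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace("=", " ").split()
        if len(parts) != 2:
            raise ParameterError(f"malformed preset line: {raw!r}")
        aliases[parts[0]] = float(parts[1])
    return table_from_aliases(aliases, name=Path(path).stem)


def write_preset_file(table: PairClassTable, path) -> None:
    lines = [f"# GBION pair-class coefficients: {table.name}"]
    d = table.as_dict()
    for key in sorted(k for k in d if k.startswith(("gi_", "intdiel_"))):
        lines.append(f"{key} {d[key]:g}")
    lines.append(f"extdiel {table.eps_out:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def available_presets() -> list[str]:
    root = resources.files("gbion") / "presets"
    return sorted(p.name[:-4] for p in root.iterdir() if p.name.endswith(".txt"))


def load_preset(name: str) -> PairClassTable:
    """Load one of the shipped pair-coefficient presets by name."""
    fname = name.lower().replace("-", "_") + ".txt"
    root = resources.files("gbion") / "presets"
    target = root / fname
    if not target.is_file():
        raise ParameterError(
            f"unknown preset {name!r}; available: {', '.join(available_presets())}")
    with resources.as_file(target) as path:
        table = read_preset_file(path)
    table.name = name
    return table


def validate_parameters(table: PairClassTable) -> dict:
    """Range diagnostics for a coefficient table.

    Hard invariants (eps_in within [1, eps_out], gamma >= 0, symmetry)
    are enforced at construction; this reports soft warnings when values
    fall outside the ranges explored during model parameterization
    (K_GB in [0, 2] i.e. gamma in [0, 8]; K_eps in [1, 78.5]).
    """

    warnings = []
    for ia in range(3):
        for ib in range(ia, 3):
            pair = f"({TOPO_CLASSES[ia]},{TOPO_CLASSES[ib]})"
            kgb = table.gamma[ia, ib] / 4.0
            if not (K_GB_RANGE[0] <= kgb <= K_GB_RANGE[1]):
                warnings.append(
                    f"gamma{pair}={table.gamma[ia, ib]:g} (K_GB={kgb:g}) is "
                    f"outside the explored range {K_GB_RANGE}")
            eps = table.eps_in[ia, ib]
            if not (K_EPS_RANGE[0] <= eps <= K_EPS_RANGE[1]):
                warnings.append(
                    f"eps_in{pair}={eps:g} is outside the explored range "
                    f"{K_EPS_RANGE}")
    return {"ok": not warnings, "warnings": warnings}
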