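"""Elements, material compositions and the bundled body-tissue library.

A material is defined by its bulk density (g/cm^3) and the mass (weight)
fractions of its constituent elements.  Twelve reference absorbers are
bundled: eleven body tissues (ICRU-44 / ICRP-89 style elemental
compositions) plus liquid water.  Composition-derived quantities such as
electrons per gram feed the Compton (Klein-Nishina) physics, which acts on
electrons and therefore scales with Z/A.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .constants import AVOGADRO

logger = logging.getLogger(__name__)

__all__ = [
    "ElementSpec",
    "MaterialComposition",
    "ELEMENTS",
    "TISSUE_NAMES",
    "load_tissue",
    "electrons_per_gram",
    "renormalize",
    "read_material",
    "write_material",
]


@dataclass(frozen=True)
class ElementSpec:
    """One chemical element: symbol, atomic number and standard atomic weight."""

    symbol: str
    Z: int
    A: float  # g/mol, IUPAC standard atomic weight

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"atomic mass must be positive, got {self.A}")


#: The twelve elements occurring in the bundled tissue compositions.
ELEMENTS: dict[str, ElementSpec] = {
    e.symbol: e
    for e in [
        ElementSpec("H", 1, 1.008),
        ElementSpec("C", 6, 12.011),
        ElementSpec("N", 7, 14.007),
        ElementSpec("O", 8, 15.999),
        ElementSpec("Na", 11, 22.98976928),
        ElementSpec("Mg", 12, 24.305),
        ElementSpec("P", 15, 30.973761998),
        ElementSpec("S", 16, 32.06),
        ElementSpec("Cl", 17, 35.45),
        ElementSpec("K", 19, 39.0983),
        ElementSpec("Ca", 20, 40.078),
        ElementSpec("Fe", 26, 55.845),
    ]
}

#: Tolerance on the sum of weight fractions before a composition is rejected.
FRACTION_SUM_TOL = 1e-3


@dataclass(frozen=True)
class MaterialComposition:
    """An absorber: name, bulk density and element weight fractions.

    Weight fractions must be non-negative and sum to one within
    :data:`FRACTION_SUM_TOL`; use :func:`renormalize` to clean up
    compositions read from external sources.
    """

    name: str
    density: float  # g/cm^3
    fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if not self.fractions:
            raise ValueError("composition has no elements")
        for sym, w in self.fractions.items():
            if sym not in ELEMENTS:
                raise KeyError(
                    f"unknown element {sym!r}; known: {sorted(ELEMENTS)}"
                )
            if w < 0:
                raise ValueError(f"negative weight fraction for {sym}: {w}")
        s = sum(self.fractions.values())
        if abs(s - 1.0) > FRACTION_SUM_TOL:
            raise ValueError(
                f"weight fractions of {self.name!r} sum to {s:.6f}, "
                f"outside 1 +/- {FRACTION_SUM_TOL}; renormalize first"
            )

    @property
    def elements(self) -> list[str]:
        return [s for s, w in self.fractions.items() if w > 0]


def renormalize(
    name: str,
    density: float,
    fractions: Mapping[str, float],
    tol: float = FRACTION_SUM_TOL,
) -> MaterialComposition:
    """Scale weight fractions to sum exactly to one.

    Deviations up to ``tol`` are silently fixed (with a log warning when any
    scaling is applied); larger deviations raise ``ValueError`` because they
    indicate a transcription error rather than rounding.
    """
    s = sum(fractions.values())
    if abs(s - 1.0) > tol:
        raise ValueError(
            f"weight fractions of {name!r} sum to {s:.6f}, "
            f"deviation {abs(s - 1.0):.2e} exceeds tol {tol:.2e}"
        )
    if s != 1.0:
        logger.warning(
            "renormalizing %r: fraction sum %.6f scaled to 1", name, s
        )
        fractions = {k: v / s for k, v in fractions.items()}
    return MaterialComposition(name=name, density=density, fractions=dict(fractions))


# Bundled absorber library: density (g/cm^3) and element weight fractions.
# Blank table cells are weight fraction zero.
_TISSUES: dict[str, MaterialComposition] = {
    m.name: m
    for m in [
        MaterialComposition("Adipose Tissue", 0.95, {
            "H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278,
            "Na": 0.001, "S": 0.001, "Cl": 0.001}),
        MaterialComposition("Blood", 1.06, {
            "H": 0.102, "C": 0.11, "N": 0.033, "O": 0.745, "Na": 0.001,
            "P": 0.001, "S": 0.002, "Cl": 0.003, "K": 0.002, "Fe": 0.001}),
        MaterialComposition("Bone (Cortical)", 1.92, {
            "H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Na": 0.001,
            "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225}),
        MaterialComposition("Brain (Grey/White Matter)", 1.04, {
            "H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712, "Na": 0.002,
            "P": 0.004, "S": 0.002, "Cl": 0.003, "K": 0.003}),
        MaterialComposition("Breast Tissue", 1.02, {
            "H": 0.106, "C": 0.332, "N": 0.03, "O": 0.527, "Na": 0.001,
            "P": 0.001, "S": 0.002, "Cl": 0.001}),
        MaterialComposition("Eye Lens", 1.07, {
            "H": 0.096, "C": 0.195, "N": 0.057, "O": 0.646, "Na": 0.001,
            "P": 0.001, "S": 0.003, "Cl": 0.001}),
        MaterialComposition("Lung Tissue", 1.05, {
            "H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749, "Na": 0.002,
            "P": 0.002, "S": 0.003, "Cl": 0.003, "K": 0.002}),
        MaterialComposition("Muscle (Skeletal)", 1.05, {
            "H": 0.102, "C": 0.143, "N": 0.034, "O": 0.71, "Na": 0.001,
            "P": 0.002, "S": 0.003, "Cl": 0.001, "K": 0.004}),
        MaterialComposition("Ovary", 1.05, {
            "H": 0.105, "C": 0.093, "N": 0.024, "O": 0.768, "Na": 0.002,
            "P": 0.002, "S": 0.002, "Cl": 0.002, "K": 0.002}),
        MaterialComposition("Soft Tissue", 1.06, {
            "H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708, "Na": 0.002,
            "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.003}),
        MaterialComposition("Testes", 1.04, {
            "H": 0.106, "C": 0.099, "N": 0.02, "O": 0.766, "Na": 0.002,
            "P": 0.001, "S": 0.002, "Cl": 0.002, "K": 0.002}),
        MaterialComposition("Water", 1.0, {"H": 0.1119, "O": 0.8881}),
    ]
}

#: Canonical names of the bundled absorbers, in library order.
TISSUE_NAMES: tuple[str, ...] = tuple(_TISSUES)


def _norm(name: str) -> str:
    """Lower-case and strip punctuation/whitespace for alias matching."""
    return re.sub(r"[^a-z0-9]+", "", name.lower())


_ALIASES: dict[str, str] = {_norm(n): n for n in _TISSUES}
_ALIASES.update({
    _norm("adipose"): "Adipose Tissue",
    _norm("bone-cortical"): "Bone (Cortical)",
    _norm("cortical bone"): "Bone (Cortical)",
    _norm("bone"): "Bone (Cortical)",
    _norm("brain"): "Brain (Grey/White Matter)",
    _norm("brain-grey/white matter"): "Brain (Grey/White Matter)",
    _norm("breast"): "Breast Tissue",
    _norm("eye lens"): "Eye Lens",
    _norm("eyelens"): "Eye Lens",
    _norm("lung"): "Lung Tissue",
    _norm("muscle"): "Muscle (Skeletal)",
    _norm("muscle-skeletal"): "Muscle (Skeletal)",
    _norm("skeletal muscle"): "Muscle (Skeletal)",
    _norm("ovaries"): "Ovary",
    _norm("soft"): "Soft Tissue",
})


def load_tissue(name: str) -> MaterialComposition:
    """Look up a bundled absorber by (case-insensitive, punctuation-blind) name.

    Raises ``KeyError`` listing the available materials if the name is
    unknown.
    """
    key = _norm(name)
    if key not in _ALIASES:
        raise KeyError(
            f"unknown material {name!r}; available: {', '.join(TISSUE_NAMES)}"
        )
    return _TISSUES[_ALIASES[key]]


def electrons_per_gram(mat: MaterialComposition) -> float:
    """Electron density of a mixture, N_A * sum_i w_i Z_i / A_i, in 1/g.

    Linear in the weight fractions, so mixing two materials 50/50 by mass
    averages their electron densities.
    """
    total = 0.0
    for sym, w in mat.fractions.items():
        try:
            el = ELEMENTS[sym]
        except KeyError:
            raise KeyError(f"element {sym!r} not in registry") from None
        total += w * el.Z / el.A
    return AVOGADRO * total


def read_material(path: str | Path) -> MaterialComposition:
    """Read a material definition from a YAML or JSON file.

    Expected keys: ``name``, ``density_g_cm3``, ``fractions`` (mapping
    element symbol -> weight fraction).  Fractions are renormalized on load
    within the standard tolerance.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    try:
        name = doc["name"]
        density = float(doc["density_g_cm3"])
        fractions = {str(k): float(v) for k, v in doc["fractions"].items()}
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed material file {path}: {exc}") from exc
    return renormalize(name, density, fractions)


def write_material(mat: MaterialComposition, path: str | Path) -> None:
    """Write a material definition as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    doc = {
        "name": mat.name,
        "density_g_cm3": mat.density,
        "fractions": {k: float(v) for k, v in mat.fractions.items() if v > 0},
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
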