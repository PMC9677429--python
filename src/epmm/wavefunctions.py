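"""Atomic core/valence spherical densities from Slater-shell tables.

The packaged table (``data/wavefunctions.txt``) lists per-shell single-zeta
Slater orbitals; shell densities are analytic sums of primitives
``c * r^p * exp(-a r)`` in Bohr units, which later gives closed-form
electrostatic potentials via incomplete gamma functions.  Alternative
wavefunction tables in the same format can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import factorial, pi
from pathlib import Path

import numpy as np

__all__ = [
    "SlaterShell",
    "SphericalPrimitive",
    "AtomicWavefunctionTable",
    "load_wavefunction_table",
    "default_wavefunction_table",
]


@dataclass(frozen=True)
class SphericalPrimitive:
    """One term ``coef * r^p * exp(-alpha r)`` of a spherical density (e/Bohr^3)."""

    coef: float
    p: int
    alpha: float

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        return self.coef * r**self.p * np.exp(-self.alpha * r)


@dataclass(frozen=True)
class SlaterShell:
    label: str
    n: int
    zeta: float
    occupation: int
    is_core: bool

    def density_primitive(self) -> SphericalPrimitive:
        """Spherically averaged shell density as a single primitive (total, not per e)."""
        n2 = (2.0 * self.zeta) ** (2 * self.n + 1) / factorial(2 * self.n)
        return SphericalPrimitive(
            coef=self.occupation * n2 / (4.0 * pi),
            p=2 * self.n - 2,
            alpha=2.0 * self.zeta,
        )


@dataclass
class AtomicWavefunctionTable:
    """Core and valence spherical densities of one element, per-electron normalized."""

    element: str
    atomic_number: int
    shells: list[SlaterShell] = field(default_factory=list)

    @property
    def n_core_electrons(self) -> int:
        return sum(s.occupation for s in self.shells if s.is_core)

    @property
    def n_valence_electrons(self) -> int:
        return sum(s.occupation for s in self.shells if not s.is_core)

    def _primitives(self, core: bool) -> list[SphericalPrimitive]:
        nel = self.n_core_electrons if core else self.n_valence_electrons
        if nel == 0:
            return []
        out = []
        for s in self.shells:
            if s.is_core is core:
                prim = s.density_primitive()
                out.append(SphericalPrimitive(prim.coef / nel, prim.p, prim.alpha))
        return out

    def core_primitives(self) -> list[SphericalPrimitive]:
        """Per-electron core density as primitives (empty for coreless atoms)."""
        return self._primitives(core=True)

    def valence_primitives(self) -> list[SphericalPrimitive]:
        return self._primitives(core=False)

    def core_density(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for p in self.core_primitives():
            out += p(r)
        return out

    def valence_density(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for p in self.valence_primitives():
            out += p(r)
        return out


def load_wavefunction_table(path) -> dict[str, AtomicWavefunctionTable]:
    tables: dict[str, AtomicWavefunctionTable] = {}
    current: AtomicWavefunctionTable | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        if tok[0] == "ELEMENT":
            current = AtomicWavefunctionTable(tok[1], int(tok[2]))
            tables[tok[1]] = current
        elif tok[0] == "SHELL":
            if current is None:
                raise ValueError("SHELL line before any ELEMENT line")
            current.shells.append(
                SlaterShell(
                    label=tok[1],
                    n=int(tok[2]),
                    zeta=float(tok[3]),
                    occupation=int(tok[4]),
                    is_core=(tok[5] == "core"),
                )
            )
        else:
            raise ValueError(f"unrecognized wavefunction-table line: {raw!r}")
    return tables


_DEFAULT: dict[str, AtomicWavefunctionTable] | None = None


def default_wavefunction_table() -> dict[str, AtomicWavefunctionTable]:
    global _DEFAULT
    if _DEFAULT is None:
        with resources.as_file(
            resources.files("epmm.data").joinpath("wavefunctions.txt")
        ) as p:
            _DEFAULT = load_wavefunction_table(p)
    return _DEFAULT
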