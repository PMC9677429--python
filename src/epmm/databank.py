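"""Pseudoatom parameter databank: atom-type keys, entries, and the file format.

Atom types are keyed by element plus the sorted multiset of bonded neighbor
elements (optionally with planarity/ring flags), a simplified stand-in for
the full topological keys of production databanks; matching falls back in a
documented specificity order:

    full key (element + neighbors)  >  element + neighbor count  >  element

File format (plain text, versioned header ``EPMM-DATABANK 1``)::

    ENTRY O_water
    KEY O H H              # full key: element, then sorted neighbors
    # KEY N COUNT 4        # count key
    # KEY Mg *             # element fallback
    PARAM P_core 2.0 P_val 6.3200 kappa 0.9800 kappa_prime 1.1500
    RADIAL zeta 2.2266 n 2 2 2 3 4
    PLM 1 0 0.1200
    FRAME auto
    END
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .density import PseudoatomParameters, RadialFunctionSpec

__all__ = ["AtomTypeKey", "DatabankEntry", "Databank", "read_databank", "write_databank"]

_KIND_FULL = "full"
_KIND_COUNT = "count"
_KIND_ELEMENT = "element"
_SPECIFICITY = {_KIND_FULL: 0, _KIND_COUNT: 1, _KIND_ELEMENT: 2}


@dataclass(frozen=True)
class AtomTypeKey:
    """Canonical (hashable) chemical-environment key."""

    element: str
    neighbors: tuple[str, ...] = ()  # sorted
    kind: str = _KIND_FULL
    neighbor_count: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "neighbors", tuple(sorted(self.neighbors)))
        if self.kind == _KIND_FULL and self.neighbor_count is None:
            object.__setattr__(self, "neighbor_count", len(self.neighbors))

    def matches(self, element: str, neighbor_elements: list[str]) -> bool:
        if element != self.element:
            return False
        if self.kind == _KIND_FULL:
            return tuple(sorted(neighbor_elements)) == self.neighbors
        if self.kind == _KIND_COUNT:
            return len(neighbor_elements) == self.neighbor_count
        return True


@dataclass
class DatabankEntry:
    name: str
    key: AtomTypeKey
    parameters: PseudoatomParameters
    frame_rule: str = "auto"
    provenance: str = ""

    @property
    def specificity(self) -> int:
        return _SPECIFICITY[self.key.kind]


@dataclass
class Databank:
    entries: list[DatabankEntry] = field(default_factory=list)
    version: str = "1"

    def elements(self) -> set[str]:
        return {e.key.element for e in self.entries}

    def lookup(self, element: str, neighbor_elements: list[str]) -> DatabankEntry:
        """Most specific matching entry; ambiguity is an error, never a tie-break."""
        if element not in self.elements():
            raise KeyError(f"element {element!r} not present in the databank")
        matches = [e for e in self.entries if e.key.matches(element, neighbor_elements)]
        if not matches:
            raise KeyError(
                f"no databank entry matches {element} with neighbors "
                f"{sorted(neighbor_elements)}"
            )
        best = min(m.specificity for m in matches)
        top = [m for m in matches if m.specificity == best]
        if len(top) > 1:
            names = ", ".join(t.name for t in top)
            raise ValueError(
                f"ambiguous databank match for {element} with neighbors "
                f"{sorted(neighbor_elements)}: {names}"
            )
        return top[0]


def write_databank(bank: Databank, path) -> None:
    lines = [f"EPMM-DATABANK {bank.version}"]
    for e in bank.entries:
        lines.append("")
        lines.append(f"ENTRY {e.name}")
        if e.key.kind == _KIND_FULL:
            lines.append(" ".join(["KEY", e.key.element, *e.key.neighbors]))
        elif e.key.kind == _KIND_COUNT:
            lines.append(f"KEY {e.key.element} COUNT {e.key.neighbor_count}")
        else:
            lines.append(f"KEY {e.key.element} *")
        p = e.parameters
        lines.append(
            f"PARAM P_core {p.p_core:.4f} P_val {p.p_val:.6f} "
            f"kappa {p.kappa:.4f} kappa_prime {p.kappa_prime:.4f}"
        )
        lines.append(
            f"RADIAL zeta {p.radial.zeta:.4f} n "
            + " ".join(str(n) for n in p.radial.n_of_l)
        )
        for (l, m), v in sorted(p.p_lm.items()):
            lines.append(f"PLM {l} {m} {v:.6f}")
        lines.append(f"FRAME {e.frame_rule}")
        if e.provenance:
            lines.append(f"PROVENANCE {e.provenance}")
        lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_databank(path) -> Databank:
    text = Path(path).read_text()
    lines = [ln.split("#", 1)[0].rstrip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines or not lines[0].startswith("EPMM-DATABANK"):
        raise ValueError("missing EPMM-DATABANK version header")
    bank = Databank(version=lines[0].split()[1])
    i = 1
    while i < len(lines):
        tok = lines[i].split()
        if tok[0] != "ENTRY":
            raise ValueError(f"expected ENTRY, got {lines[i]!r}")
        name = tok[1]
        key = None
        fields: dict = {"p_lm": {}, "frame_rule": "auto", "provenance": ""}
        i += 1
        while i < len(lines) and lines[i].strip() != "END":
            tok = lines[i].split()
            if tok[0] == "KEY":
                if len(tok) >= 3 and tok[2] == "COUNT":
                    key = AtomTypeKey(tok[1], kind=_KIND_COUNT, neighbor_count=int(tok[3]))
                elif len(tok) >= 3 and tok[2] == "*":
                    key = AtomTypeKey(tok[1], kind=_KIND_ELEMENT)
                else:
                    key = AtomTypeKey(tok[1], tuple(tok[2:]))
            elif tok[0] == "PARAM":
                kv = dict(zip(tok[1::2], tok[2::2]))
                fields.update(
                    p_core=float(kv["P_core"]),
                    p_val=float(kv["P_val"]),
                    kappa=float(kv["kappa"]),
                    kappa_prime=float(kv["kappa_prime"]),
                )
            elif tok[0] == "RADIAL":
                fields["radial"] = RadialFunctionSpec(
                    zeta=float(tok[2]), n_of_l=tuple(int(x) for x in tok[4:9])
                )
            elif tok[0] == "PLM":
                fields["p_lm"][(int(tok[1]), int(tok[2]))] = float(tok[3])
            elif tok[0] == "FRAME":
                fields["frame_rule"] = " ".join(tok[1:])
            elif tok[0] == "PROVENANCE":
                fields["provenance"] = " ".join(tok[1:])
            else:
                raise ValueError(f"unrecognized databank line: {lines[i]!r}")
            i += 1
        if i >= len(lines):
            raise ValueError(f"entry {name!r} not terminated by END")
        if key is None:
            raise ValueError(f"entry {name!r} has no KEY line")
        params = PseudoatomParameters(
            element=key.element,
            p_core=fields["p_core"],
            p_val=fields["p_val"],
            kappa=fields["kappa"],
            kappa_prime=fields["kappa_prime"],
            radial=fields["radial"],
            p_lm=fields["p_lm"],
        )
        bank.entries.append(
            DatabankEntry(
                name=name,
                key=key,
                parameters=params,
                frame_rule=fields["frame_rule"],
                provenance=fields["provenance"],
            )
        )
        i += 1
    return bank
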