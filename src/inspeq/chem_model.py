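"""Equilibrium species data model and packaged chemical models.

A :class:`ChemicalModel` is a set of mononuclear complex species of one
ligand L, each defined by its stoichiometry in protons (``n_h``),
potassium (``n_k``) and magnesium (``n_mg``), together with a cumulative
formation constant ``log_beta`` (log10, molar concentration scale)
referenced to the fully deprotonated free ligand and the free ions:

    h H+  +  k K+  +  m Mg2+  +  L  <->  [Mg_m K_k (H_h L)]

Constants refer to a constant ionic medium (no activity-coefficient
corrections) and to the temperature recorded in ``medium``; using them at
other temperatures is a documented approximation.

Model documents are small human-editable text files (see
:func:`loads_model`); validated ligand models ship with the package and
are available through :func:`load_builtin`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping

__all__ = [
    "CONFORMERS",
    "SpeciesDef",
    "ChemicalModel",
    "ModelDocumentError",
    "species_charge",
    "count_species",
    "load_model",
    "loads_model",
    "dump_model",
    "dumps_model",
    "load_builtin",
    "builtin_model_names",
]

CONFORMERS = ("axial", "equatorial", "unspecified")

#: subscript-free ASCII display is used throughout (e.g. "[MgK3(H3L)]^6-")
_SIGN = {1: "+", -1: "-"}


class ModelDocumentError(ValueError):
    """Raised for malformed or internally inconsistent model documents."""


def species_charge(species: "SpeciesDef", base_charge: int) -> int:
    """Net charge of a species given the free-ligand base charge.

    charge = base_charge * n_l + n_h + n_k + 2 * n_mg
    """
    return base_charge * species.n_l + species.n_h + species.n_k + 2 * species.n_mg


def _format_charge(charge: int) -> str:
    if charge == 0:
        return ""
    sign = _SIGN[1 if charge > 0 else -1]
    return f"^{abs(charge)}{sign}"


@dataclass(frozen=True)
class SpeciesDef:
    """One complex species: stoichiometry plus cumulative formation constant."""

    id: str
    n_h: int
    n_k: int
    n_mg: int
    log_beta: float
    n_l: int = 1
    conformer: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ModelDocumentError(f"invalid species id {self.id!r}")
        for name in ("n_h", "n_k", "n_mg"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ModelDocumentError(f"{self.id}: {name} must be a nonnegative integer, got {v!r}")
        if self.n_l not in (0, 1):
            raise ModelDocumentError(f"{self.id}: n_l must be 0 or 1, got {self.n_l!r}")
        if not math.isfinite(self.log_beta):
            raise ModelDocumentError(f"{self.id}: log_beta must be finite")
        if self.conformer not in CONFORMERS:
            raise ModelDocumentError(
                f"{self.id}: conformer must be one of {CONFORMERS}, got {self.conformer!r}"
            )

    @property
    def is_free_ligand(self) -> bool:
        return self.n_l == 1 and self.n_h == 0 and self.n_k == 0 and self.n_mg == 0

    def charge(self, base_charge: int) -> int:
        return species_charge(self, base_charge)

    def display_name(self, base_charge: int) -> str:
        """Formatted name, e.g. ``[MgK3(H3L)]^6-`` or ``H5L^9-``."""
        charge = _format_charge(self.charge(base_charge))
        core = "L" if self.n_h == 0 else ("HL" if self.n_h == 1 else f"H{self.n_h}L")
        if self.n_k == 0 and self.n_mg == 0:
            return core + charge
        mg = "" if self.n_mg == 0 else ("Mg" if self.n_mg == 1 else f"Mg{self.n_mg}")
        k = "" if self.n_k == 0 else ("K" if self.n_k == 1 else f"K{self.n_k}")
        inner = core if self.n_h == 0 else f"({core})"
        return f"[{mg}{k}{inner}]{charge}"


@dataclass(frozen=True)
class ChemicalModel:
    """A validated set of species for one ligand."""

    ligand_name: str
    base_ligand_charge: int
    species: tuple[SpeciesDef, ...]
    medium: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        ids = [s.id for s in self.species]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ModelDocumentError(f"duplicate species ids: {sorted(dupes)}")
        free = [s for s in self.species if s.is_free_ligand]
        if len(free) != 1:
            raise ModelDocumentError(
                f"model must contain exactly one free-ligand species, found {len(free)}"
            )
        if free[0].log_beta != 0.0:
            raise ModelDocumentError("free ligand must have log_beta = 0 by convention")

    # -- access ---------------------------------------------------------

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    def get(self, species_id: str) -> SpeciesDef:
        for s in self.species:
            if s.id == species_id:
                return s
        raise KeyError(species_id)

    @property
    def free_ligand(self) -> SpeciesDef:
        return next(s for s in self.species if s.is_free_ligand)

    def display(self, species_id: str) -> str:
        return self.get(species_id).display_name(self.base_ligand_charge)

    # -- derived models -------------------------------------------------

    def subset(self, predicate: Callable[[SpeciesDef], bool], name: str | None = None) -> "ChemicalModel":
        """Sub-model of species matching ``predicate``; free ligand is always kept."""
        kept = tuple(s for s in self.species if s.is_free_ligand or predicate(s))
        return replace(self, species=kept, ligand_name=name or self.ligand_name)

    def protonation_only(self) -> "ChemicalModel":
        return self.subset(lambda s: s.n_k == 0 and s.n_mg == 0)

    def with_log_betas(self, values: Mapping[str, float]) -> "ChemicalModel":
        """Copy of the model with selected cumulative constants replaced."""
        unknown = set(values) - set(self.ids)
        if unknown:
            raise KeyError(f"unknown species ids: {sorted(unknown)}")
        new = tuple(
            replace(s, log_beta=float(values[s.id])) if s.id in values else s
            for s in self.species
        )
        return replace(self, species=new)

    # -- derived constants ----------------------------------------------

    def protonation_ladder(self) -> tuple[SpeciesDef, ...]:
        """Metal-free species ordered by proton count (free L first)."""
        ladder = [s for s in self.species if s.n_k == 0 and s.n_mg == 0]
        return tuple(sorted(ladder, key=lambda s: s.n_h))

    def stepwise_protonation_log_k(self) -> dict[int, float]:
        """Stepwise log K of H(n-1)L + H+ <-> HnL for consecutive ladder states."""
        ladder = self.protonation_ladder()
        out: dict[int, float] = {}
        for prev, cur in zip(ladder, ladder[1:]):
            if cur.n_h == prev.n_h + 1:
                out[cur.n_h] = cur.log_beta - prev.log_beta
        return out

    def stepwise_metal_log_k(self, species_id: str) -> float:
        """log K of the metal-binding step  m Mg + k K + H_hL <-> [Mg_m K_k (H_h L)].

        Derived from the cumulative constants: log_beta(complex) minus
        log_beta of the bare protonation state with the same proton count.
        """
        sp = self.get(species_id)
        if sp.n_k == 0 and sp.n_mg == 0:
            raise ValueError(f"{species_id} is not a metal complex")
        parent = next(
            (s for s in self.species if s.n_k == 0 and s.n_mg == 0 and s.n_h == sp.n_h),
            None,
        )
        if parent is None:
            raise ValueError(f"no H{sp.n_h}L parent state in model for {species_id}")
        return sp.log_beta - parent.log_beta


def count_species(model: ChemicalModel, predicate: Callable[[SpeciesDef], bool]) -> int:
    """Number of species in ``model`` matching ``predicate``."""
    return sum(1 for s in model.species if predicate(s))


# ---------------------------------------------------------------------------
# model document format
# ---------------------------------------------------------------------------
#
#   ligand: InsP8
#   base_charge: -14
#   medium: I = 0.15 M; T = 22 C
#
#   [species]
#   # id      n_h  n_k  n_mg  log_beta  conformer    charge
#   L         0    0    0     0.0       unspecified  -14
#   ...
#
# The trailing ``charge`` column is redundant and is validated against the
# charge formula; a mismatch rejects the document.

_HEADER_KEYS = {"ligand", "base_charge", "medium"}


def loads_model(text: str, source: str = "<string>") -> ChemicalModel:
    """Parse and validate a model document."""
    header: dict[str, str] = {}
    species: list[SpeciesDef] = []
    declared_charges: list[tuple[str, int]] = []
    in_species = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower() == "[species]":
            in_species = True
            continue
        if not in_species:
            key, sep, val = line.partition(":")
            key = key.strip().lower()
            if not sep or key not in _HEADER_KEYS:
                raise ModelDocumentError(f"{source}:{lineno}: unrecognized header line {raw!r}")
            header[key] = val.strip()
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ModelDocumentError(
                f"{source}:{lineno}: expected 7 columns (id n_h n_k n_mg log_beta conformer charge)"
            )
        sid, n_h, n_k, n_mg, log_beta, conformer, charge = parts
        try:
            sp = SpeciesDef(
                id=sid,
                n_h=int(n_h),
                n_k=int(n_k),
                n_mg=int(n_mg),
                log_beta=float(log_beta),
                conformer=conformer,
            )
            declared_charges.append((sid, int(charge)))
        except (ModelDocumentError, ValueError) as exc:
            raise ModelDocumentError(f"{source}:{lineno}: {exc}") from exc
        species.append(sp)

    for key in ("ligand", "base_charge"):
        if key not in header:
            raise ModelDocumentError(f"{source}: missing header field {key!r}")
    try:
        base_charge = int(header["base_charge"])
    except ValueError as exc:
        raise ModelDocumentError(f"{source}: base_charge must be an integer") from exc

    for sp, (sid, declared) in zip(species, declared_charges):
        computed = sp.charge(base_charge)
        if computed != declared:
            raise ModelDocumentError(
                f"{source}: species {sid}: declared charge {declared} does not match "
                f"{base_charge}*{sp.n_l} + {sp.n_h} + {sp.n_k} + 2*{sp.n_mg} = {computed}"
            )
    return ChemicalModel(
        ligand_name=header["ligand"],
        base_ligand_charge=base_charge,
        species=tuple(species),
        medium=header.get("medium", ""),
    )


def load_model(path: str | Path) -> ChemicalModel:
    """Load a model document from ``path``."""
    p = Path(path)
    return loads_model(p.read_text(encoding="utf-8"), source=str(p))


def dumps_model(model: ChemicalModel) -> str:
    lines = [
        f"ligand: {model.ligand_name}",
        f"base_charge: {model.base_ligand_charge}",
        f"medium: {model.medium}",
        "",
        "[species]",
        "# id\tn_h\tn_k\tn_mg\tlog_beta\tconformer\tcharge",
    ]
    for s in model.species:
        lines.append(
            f"{s.id}\t{s.n_h}\t{s.n_k}\t{s.n_mg}\t{s.log_beta:.6g}\t{s.conformer}\t"
            f"{s.charge(model.base_ligand_charge)}"
        )
    return "\n".join(lines) + "\n"


def dump_model(model: ChemicalModel, path: str | Path) -> None:
    Path(path).write_text(dumps_model(model), encoding="utf-8")


def builtin_model_names() -> tuple[str, ...]:
    files = resources.files("inspeq.data")
    return tuple(sorted(p.name[: -len(".model")] for p in files.iterdir() if p.name.endswith(".model")))


def load_builtin(name: str) -> ChemicalModel:
    """Load a packaged ligand model by name (e.g. ``"insp8"``)."""
    res = resources.files("inspeq.data") / f"{name}.model"
    try:
        text = res.read_text(encoding="utf-8")
    except FileNotFoundError as exc:
        raise KeyError(f"no packaged model {name!r}; available: {builtin_model_names()}") from exc
    return loads_model(text, source=f"builtin:{name}")
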