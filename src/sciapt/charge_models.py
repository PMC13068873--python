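"""Functional-charge models of the target lipid and the aptamer building blocks.

The design method treats a drug-target complex as a many-charge system: each
molecule is reduced to its functional charge sites (full charges of +/-1 e on
ionized groups such as PO4-, NH3+ and CO2-, and partial charges of magnitude
``delta`` on polarized H/N/O sites).  This module defines those descriptions,
loads the packaged defaults for phosphatidylserine (PS) and the five
nucleotides A, G, C, T, U, and lets users override or extend them from a
human-editable YAML file.

The packaged models place the nucleotides in two charge-distribution classes:
G and C carry four functional charges, while A, T and U carry three.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Mapping, Union

import yaml

__all__ = [
    "ChargeSite",
    "BiomoleculeChargeModel",
    "ModelRegistry",
    "ChargeModelError",
    "load_registry",
    "charge_site_count",
    "nucleotide_class",
    "DEFAULT_DELTA",
    "PURINES",
    "PYRIMIDINES",
]

#: Magnitude of a partial charge, in units of e.  A typical scale for
#: polarized H/N/O sites; only relative energies enter ABB selection.
DEFAULT_DELTA = 0.2

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "T", "U"})

_MOL_CLASSES = ("lipid", "purine", "pyrimidine")
_NET_SIGNS = ("negative", "positive", "neutral")


class ChargeModelError(ValueError):
    """Raised for malformed or inconsistent charge-model definitions."""


@dataclass(frozen=True)
class ChargeSite:
    """A single functional charge: a label and a signed magnitude in e."""

    label: str
    charge: float

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ChargeModelError(f"site {self.label!r}: charge must be nonzero")
        if abs(self.charge) > 1.0:
            raise ChargeModelError(
                f"site {self.label!r}: |charge| = {abs(self.charge)} exceeds 1 e"
            )


@dataclass(frozen=True)
class BiomoleculeChargeModel:
    """A named molecule with its ordered charge sites, class and axial size."""

    name: str
    mol_class: str
    sites: tuple[ChargeSite, ...]
    axial_size: float
    net_sign: str

    def __post_init__(self) -> None:
        if self.mol_class not in _MOL_CLASSES:
            raise ChargeModelError(
                f"{self.name}: mol_class {self.mol_class!r} not in {_MOL_CLASSES}"
            )
        if self.net_sign not in _NET_SIGNS:
            raise ChargeModelError(
                f"{self.name}: net_sign {self.net_sign!r} not in {_NET_SIGNS}"
            )
        if not self.sites:
            raise ChargeModelError(f"{self.name}: at least one charge site required")
        if self.axial_size <= 0:
            raise ChargeModelError(f"{self.name}: axial_size must be positive")
        total = self.net_charge
        sign = "neutral" if abs(total) < 1e-12 else ("negative" if total < 0 else "positive")
        if sign != self.net_sign:
            raise ChargeModelError(
                f"{self.name}: summed site charge {total:+.3f} e is {sign}, "
                f"contradicting declared net_sign {self.net_sign!r}"
            )

    @property
    def net_charge(self) -> float:
        """Sum of site charges, in e."""
        return sum(s.charge for s in self.sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class ModelRegistry:
    """All known charge models, plus the ordered nucleotide alphabet."""

    models: dict[str, BiomoleculeChargeModel]
    alphabet: tuple[str, ...] = ("A", "G", "C", "T", "U")
    delta: float = DEFAULT_DELTA
    lengths: dict[str, float] = field(
        default_factory=lambda: {"a_Pu": 0.34, "a_Py": 0.30, "ps_span": 0.90}
    )

    def __post_init__(self) -> None:
        if len(self.alphabet) != 5:
            raise ChargeModelError("alphabet must have exactly 5 nucleotides")
        for sym in self.alphabet:
            m = self.models.get(sym)
            if m is None:
                raise ChargeModelError(f"alphabet entry {sym!r} has no charge model")
            if m.mol_class not in ("purine", "pyrimidine"):
                raise ChargeModelError(
                    f"alphabet entry {sym!r} has mol_class {m.mol_class!r}"
                )

    def __getitem__(self, name: str) -> BiomoleculeChargeModel:
        try:
            return self.models[name]
        except KeyError:
            raise KeyError(f"no charge model named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.models

    def __len__(self) -> int:
        return len(self.models)

    def to_json(self) -> str:
        """Serialize the registry for provenance logging (round-trips)."""
        payload = {
            "delta": self.delta,
            "alphabet": list(self.alphabet),
            "lengths": dict(self.lengths),
            "molecules": {
                m.name: {
                    "mol_class": m.mol_class,
                    "net_sign": m.net_sign,
                    "axial_size": m.axial_size,
                    "sites": [{"label": s.label, "charge": s.charge} for s in m.sites],
                }
                for m in self.models.values()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelRegistry":
        d = json.loads(text)
        models = {
            name: BiomoleculeChargeModel(
                name=name,
                mol_class=rec["mol_class"],
                sites=tuple(ChargeSite(s["label"], float(s["charge"])) for s in rec["sites"]),
                axial_size=float(rec["axial_size"]),
                net_sign=rec["net_sign"],
            )
            for name, rec in d["molecules"].items()
        }
        return cls(
            models=models,
            alphabet=tuple(d["alphabet"]),
            delta=float(d["delta"]),
            lengths={k: float(v) for k, v in d["lengths"].items()},
        )


def _resolve_charge(raw: object, delta: float, where: str) -> float:
    if isinstance(raw, str):
        token = raw.strip().lower()
        if token in ("+delta", "delta"):
            return delta
        if token == "-delta":
            return -delta
        raise ChargeModelError(f"{where}: unrecognized charge token {raw!r}")
    try:
        return float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ChargeModelError(f"{where}: charge {raw!r} is not a number") from None


def _axial_size(name: str, mol_class: str, rec: Mapping, lengths: Mapping[str, float]) -> float:
    if "axial_size" in rec:
        return float(rec["axial_size"])
    if mol_class == "purine":
        return lengths["a_Pu"]
    if mol_class == "pyrimidine":
        return lengths["a_Py"]
    if mol_class == "lipid" and "ps_span" in lengths:
        return lengths["ps_span"]
    raise ChargeModelError(f"{name}: axial_size required for mol_class {mol_class!r}")


def _parse_document(doc: Mapping, base: dict | None = None) -> ModelRegistry:
    if not isinstance(doc, Mapping):
        raise ChargeModelError("charge-model document must be a mapping")
    merged: dict = {
        "delta": DEFAULT_DELTA,
        "lengths": {"a_Pu": 0.34, "a_Py": 0.30, "ps_span": 0.90},
        "alphabet": ["A", "G", "C", "T", "U"],
        "molecules": {},
    }
    if base:
        merged["delta"] = base["delta"]
        merged["lengths"].update(base["lengths"])
        merged["alphabet"] = list(base["alphabet"])
        merged["molecules"].update(base["molecules"])
    if "delta" in doc:
        merged["delta"] = float(doc["delta"])
    if "lengths" in doc:
        merged["lengths"].update({k: float(v) for k, v in doc["lengths"].items()})
    if "alphabet" in doc:
        merged["alphabet"] = list(doc["alphabet"])
    for name, rec in (doc.get("molecules") or {}).items():
        merged["molecules"][name] = dict(rec)

    delta = merged["delta"]
    lengths = merged["lengths"]
    models: dict[str, BiomoleculeChargeModel] = {}
    for name, rec in merged["molecules"].items():
        try:
            mol_class = rec["mol_class"]
            raw_sites = rec["sites"]
        except KeyError as exc:
            raise ChargeModelError(f"molecule {name!r}: missing key {exc}") from None
        sites = tuple(
            ChargeSite(
                label=str(s["label"]),
                charge=_resolve_charge(s["charge"], delta, f"{name}/{s.get('label')}"),
            )
            for s in raw_sites
        )
        models[name] = BiomoleculeChargeModel(
            name=name,
            mol_class=mol_class,
            sites=sites,
            axial_size=_axial_size(name, mol_class, rec, lengths),
            net_sign=rec.get("net_sign", "negative"),
        )
    return ModelRegistry(
        models=models,
        alphabet=tuple(merged["alphabet"]),
        delta=delta,
        lengths=lengths,
    )


def _packaged_document() -> dict:
    text = resources.files("sciapt.data").joinpath("charge_models.yaml").read_text()
    return yaml.safe_load(text)


def load_registry(
    config_source: Union[str, Path, IO[str], Mapping, None] = None,
) -> ModelRegistry:
    """Load the charge-model registry.

    With no argument, returns the packaged defaults (PS plus the five
    nucleotides).  A path, open file, YAML string or mapping overrides or
    extends the packaged models by name; ``delta``, ``lengths`` and
    ``alphabet`` keys override the corresponding defaults, and partial-site
    charges written as ``+delta`` / ``-delta`` track the (possibly
    overridden) ``delta``.
    """
    packaged = _parse_document(_packaged_document())
    if config_source is None:
        return packaged

    if isinstance(config_source, Mapping):
        doc = config_source
    else:
        if isinstance(config_source, Path):
            text = config_source.read_text()
        elif isinstance(config_source, str):
            p = Path(config_source)
            text = p.read_text() if (len(config_source) < 4096 and p.is_file()) else config_source
        else:
            text = config_source.read()
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ChargeModelError(f"could not parse charge-model config: {exc}") from exc
        if doc is None:
            return packaged
    base_doc = _packaged_document()
    # re-parse packaged molecules raw so delta overrides re-resolve tokens
    merged_base = {
        "delta": base_doc.get("delta", DEFAULT_DELTA),
        "lengths": base_doc.get("lengths", {}),
        "alphabet": base_doc.get("alphabet", ["A", "G", "C", "T", "U"]),
        "molecules": base_doc.get("molecules", {}),
    }
    return _parse_document(doc, base=merged_base)


def charge_site_count(model: BiomoleculeChargeModel) -> int:
    """Number of functional charge sites the molecule carries."""
    return model.n_sites


def nucleotide_class(symbol: str) -> str:
    """Classify a nucleotide as ``"purine"`` (A, G) or ``"pyrimidine"`` (C, T, U)."""
    if symbol in PURINES:
        return "purine"
    if symbol in PYRIMIDINES:
        return "pyrimidine"
    raise KeyError(f"unknown nucleotide symbol {symbol!r}")
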