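"""Run configuration, the end-to-end design pipeline, and standard-format output.

``run_pipeline`` composes the stages — candidate-matrix construction (greedy
or calibration), enumeration, categorization/length/energy scoring, and
per-category ranking — and writes a FASTA of the finalized sequences, a CSV
of all candidates, and a JSON manifest recording every numeric setting that
affects the result.  Runs are deterministic: the same configuration yields
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .charge_models import ModelRegistry, load_registry
from .design import (
    AptamerCandidate,
    CandidateMatrix,
    enumerate_candidates,
    greedy_design,
    nucleic_specificity_onset,
    rank_by_energy_per_length,
    score_candidate,
)
from .geometry import LengthModel
from .sci_energy import ScreeningParams, default_scale_grid

__all__ = [
    "RunConfig",
    "DesignResult",
    "run_pipeline",
    "write_fasta",
    "load_calibration_matrix",
    "packaged_ps_calibration",
]

log = logging.getLogger("sciapt")


@dataclass
class RunConfig:
    """Everything a design run depends on."""

    target_name: str = "PS"
    n_abb: int = 10
    a_Pu: float = 0.34
    a_Py: float = 0.30
    eps_r: float = 80.0
    lambda_D: float = 1.0
    energy_unit: str = "eV"
    sweep_start: float = 0.5
    sweep_stop: float = 5.0
    sweep_num: int = 181
    tie_tol: float = 0.01
    exclude_hybrids: bool = True
    calibration_matrix: str | None = None  # path, or "packaged:PS"
    charge_config: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_abb < 1:
            raise ValueError("n_abb must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def length_model(self) -> LengthModel:
        return LengthModel(a_Pu=self.a_Pu, a_Py=self.a_Py)

    def screening_params(self) -> ScreeningParams:
        return ScreeningParams(
            eps_r=self.eps_r, lambda_D=self.lambda_D, energy_unit=self.energy_unit
        )

    def scale_grid(self):
        return default_scale_grid(self.sweep_start, self.sweep_stop, self.sweep_num)


@dataclass
class DesignResult:
    """Matrix, all scored candidates, finalized per-category set, manifest."""

    matrix: CandidateMatrix
    candidates: list[AptamerCandidate]
    finalized: dict[str, list[AptamerCandidate]]
    manifest: dict = field(default_factory=dict)

    @property
    def finalized_flat(self) -> list[AptamerCandidate]:
        seen, out = set(), []
        for cat in ("universal", "dna", "rna", "hybrid"):
            for c in self.finalized.get(cat, []):
                key = str(c.seq)
                if key not in seen:
                    seen.add(key)
                    out.append(c)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "seq": str(c.seq),
                "category": c.category,
                "n_Pu": c.seq.n_Pu,
                "n_Py": c.seq.n_Py,
                "length_nm": c.length_nm,
                "total_log_energy": c.total_log_energy,
                "score": c.score,
            }
            for c in self.candidates
        ]
        return pd.DataFrame(rows)


def load_calibration_matrix(source: str | Path) -> CandidateMatrix:
    """Read a per-order candidate matrix from YAML (key ``matrix``: list of lists)."""
    if isinstance(source, str) and source.startswith("packaged:"):
        name = source.split(":", 1)[1]
        if name != "PS":
            raise ValueError(f"no packaged calibration matrix for target {name!r}")
        return packaged_ps_calibration()
    doc = yaml.safe_load(Path(source).read_text())
    return CandidateMatrix(per_order=tuple(tuple(row) for row in doc["matrix"]))


def packaged_ps_calibration() -> CandidateMatrix:
    """The published 10-order candidate matrix for phosphatidylserine."""
    text = resources.files("sciapt.data").joinpath("ps_calibration.yaml").read_text()
    doc = yaml.safe_load(text)
    return CandidateMatrix(per_order=tuple(tuple(row) for row in doc["matrix"]))


def write_fasta(cands: Sequence[AptamerCandidate], path: str | Path) -> Path:
    """One record per candidate; header carries id, category, length and score."""
    if not cands:
        raise ValueError("no candidates to write")
    records = []
    for k, c in enumerate(cands, start=1):
        records.append(
            SeqRecord(
                Seq(str(c.seq)),
                id=f"Apt{k}",
                description=(
                    f"category={c.category} length_nm={c.length_nm:.2f} "
                    f"score={c.score:.6f}"
                ),
            )
        )
    path = Path(path)
    with path.open("w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def run_pipeline(cfg: RunConfig, registry: ModelRegistry | None = None) -> DesignResult:
    """Execute matrix -> enumeration -> scoring -> ranking, writing outputs if asked."""
    registry = registry or load_registry(cfg.charge_config)
    target = registry[cfg.target_name]
    lm = cfg.length_model()
    sp = cfg.screening_params()
    grid = cfg.scale_grid()

    stage = "matrix"
    try:
        if cfg.calibration_matrix:
            matrix = load_calibration_matrix(cfg.calibration_matrix)
            if matrix.n_orders != cfg.n_abb:
                raise ValueError(
                    f"calibration matrix has {matrix.n_orders} orders, config n_abb={cfg.n_abb}"
                )
        else:
            matrix = greedy_design(
                target, cfg.n_abb, registry, sp=sp, lm=lm,
                tie_tol=cfg.tie_tol, scale_grid=grid,
            )
        for i, opts in enumerate(matrix.per_order):
            log.info("order %d candidates: %s", i, "/".join(opts))

        stage = "enumeration"
        seqs = enumerate_candidates(
            matrix, exclude_hybrids=cfg.exclude_hybrids, alphabet=registry.alphabet
        )

        stage = "scoring"
        candidates = [
            score_candidate(s, target, registry, sp=sp, lm=lm, scale_grid=grid)
            for s in seqs
        ]

        stage = "ranking"
        finalized = rank_by_energy_per_length(candidates, tie_tol=cfg.tie_tol)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    onset = nucleic_specificity_onset(seqs) if len(seqs) >= 2 else None
    manifest = {
        "config": asdict(cfg),
        "registry_delta": registry.delta,
        "matrix": [list(opts) for opts in matrix.per_order],
        "n_candidates": len(candidates),
        "n_finalized": len(
            {str(c.seq) for cs in finalized.values() for c in cs}
        ),
        "nucleic_specificity_onset": onset,
    }
    result = DesignResult(
        matrix=matrix, candidates=candidates, finalized=finalized, manifest=manifest
    )

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            df = result.to_frame()
            csv_path = out / "candidates.csv"
            df.to_csv(csv_path, index=False, float_format="%.8f")
            written.append(csv_path)
            fasta_path = out / "finalized.fasta"
            write_fasta(result.finalized_flat, fasta_path)
            written.append(fasta_path)
            manifest_path = out / "manifest.json"
            manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
            written.append(manifest_path)
        except Exception:
            for p in written:  # no partial outputs
                p.unlink(missing_ok=True)
            raise
    return result
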