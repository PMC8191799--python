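"""Combined scan -> predict (-> fit / classify) workflow with JSON reports.

The pipeline glues the scanner and the rule engine (and, when the data are
provided, the FRET fit and the structural classifier) into one reproducible
run: every stochastic step receives an explicit or defaulted seed which is
recorded in the report, warnings are surfaced in the report itself rather
than only on the log, and a stage failure is reported with its stage name
while downstream stages are skipped.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Any

from . import __version__
from .core import KTurnError, read_fasta
from .fret import fit_two_state, read_titration_csv
from .rules import ConformationTable, predict
from .scanner import ScanConfig, scan_duplex, scan_secondary_structure
from .structure import ResidueMap, classify_N3_N1, read_structure

logger = logging.getLogger("kturn")

REPORT_SCHEMA = {
    "type": "object",
    "required": ["tool", "version", "config", "stages", "warnings"],
    "properties": {
        "tool": {"type": "string"},
        "version": {"type": "string"},
        "config": {"type": "object"},
        "stages": {"type": "object"},
        "warnings": {"type": "array", "items": {"type": "string"}},
        "error": {"type": ["object", "null"]},
    },
}


def run_pipeline(
    fasta: str | Path,
    self_dimer: bool = False,
    second_fasta: str | Path | None = None,
    dot_bracket: str | None = None,
    scan_config: ScanConfig | None = None,
    conformation_table: ConformationTable | None = None,
    titration_csv: str | Path | None = None,
    titration_units: str | None = None,
    structure_path: str | Path | None = None,
    residue_map: ResidueMap | None = None,
    seed: int = 0,
) -> dict[str, Any]:
    """Run scan -> predict and optionally fit / classify; return the report.

    Exactly one pairing mode applies: ``self_dimer`` scans the first FASTA
    record against itself, ``second_fasta`` supplies the partner strand, and
    ``dot_bracket`` a secondary structure for the single sequence.  The
    returned report is a JSON-serializable dict embedding tool version,
    configuration, per-stage outputs, rule traces, and collected warnings;
    on a stage failure the report carries {"error": {"stage": ..., ...}} and
    downstream stages are skipped.
    """
    scan_config = scan_config or ScanConfig()
    report: dict[str, Any] = {
        "tool": "kturn",
        "version": __version__,
        "config": {
            "fasta": str(fasta),
            "self_dimer": self_dimer,
            "second_fasta": str(second_fasta) if second_fasta else None,
            "dot_bracket": dot_bracket,
            "min_c_pairs": scan_config.min_c_pairs,
            "min_nc_pairs": scan_config.min_nc_pairs,
            "titration_csv": str(titration_csv) if titration_csv else None,
            "structure": str(structure_path) if structure_path else None,
            "seed": seed,
        },
        "stages": {},
        "warnings": [],
        "error": None,
    }

    def fail(stage: str, exc: Exception) -> dict[str, Any]:
        logger.error("stage %s failed: %s", stage, exc)
        report["error"] = {"stage": stage, "message": str(exc), "type": type(exc).__name__}
        return report

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # -- scan ---------------------------------------------------------
        try:
            records = read_fasta(fasta)
            if not records:
                raise KTurnError(f"no sequences in {fasta}")
            name, seq = records[0]
            if dot_bracket is not None:
                annotations = scan_secondary_structure(seq, dot_bracket, scan_config)
            else:
                if second_fasta is not None:
                    partner_records = read_fasta(second_fasta)
                    if not partner_records:
                        raise KTurnError(f"no sequences in {second_fasta}")
                    partner = partner_records[0][1]
                elif self_dimer:
                    partner = seq
                else:
                    raise KTurnError(
                        "choose a pairing mode: --self-dimer, --second or --dot-bracket"
                    )
                annotations = scan_duplex(seq, partner, scan_config)
            report["stages"]["scan"] = {
                "sequence_id": name,
                "n_kturns": len(annotations),
                "annotations": [
                    {**a.to_dict(), "nomenclature": {
                        label: {"strand": role, "base": base, "seq_index": idx}
                        for label, (role, base, idx) in a.nomenclature_table().items()
                    }}
                    for a in annotations
                ],
            }
        except Exception as e:  # noqa: BLE001 - report, don't crash the CLI
            report["warnings"].extend(str(w.message) for w in caught)
            return fail("scan", e)

        # -- predict ------------------------------------------------------
        try:
            preds = [predict(a, conformation_table) for a in annotations]
            report["stages"]["predict"] = [p.to_dict() for p in preds]
        except Exception as e:  # noqa: BLE001
            report["warnings"].extend(str(w.message) for w in caught)
            return fail("predict", e)

        # -- fit ----------------------------------------------------------
        if titration_csv is not None:
            try:
                points = read_titration_csv(titration_csv, units=titration_units)
                fit = fit_two_state(points)
                report["stages"]["fit"] = fit.to_dict()
            except Exception as e:  # noqa: BLE001
                report["warnings"].extend(str(w.message) for w in caught)
                return fail("fit", e)

        # -- classify -----------------------------------------------------
        if structure_path is not None:
            try:
                if residue_map is None:
                    raise KTurnError("structure classification requires a residue map")
                model = read_structure(structure_path)
                geom = classify_N3_N1(model, residue_map)
                report["stages"]["classify"] = geom.to_dict()
            except Exception as e:  # noqa: BLE001
                report["warnings"].extend(str(w.message) for w in caught)
                return fail("classify", e)

        report["warnings"].extend(str(w.message) for w in caught)

    return report


def write_report(report: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
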