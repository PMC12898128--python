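"""Cohort report assembly: per-module result tables plus provenance.

The report body is a pure function of its inputs and configuration;
re-running on identical inputs yields byte-identical TSV and JSON output
(the provenance block records a config hash, seed and input digests, no
timestamps). TSV is the authoritative format; the JSON mirror carries the
same tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import pandas as pd

from . import __version__


@dataclass
class CohortReport:
    sections: Dict[str, pd.DataFrame]
    provenance: Dict[str, str]

    def to_tsv_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in sorted(self.sections):
            self.sections[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "sections": {
                name: self.sections[name].to_dict(orient="records")
                for name in sorted(self.sections)
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _digest(obj: object) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def build_report(
    sections: Mapping[str, pd.DataFrame],
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
    known_ids: Optional[set] = None,
) -> CohortReport:
    """Assemble per-module tables into one deterministic report.

    Sections absent from ``sections`` are omitted, not emitted as nulls.
    If ``known_ids`` is given, any ``sequence_id``/``protein_id`` value
    outside it is treated as a conflict and reported in the error.
    """
    if not sections:
        raise ValueError("at least one module result table is required")
    if known_ids is not None:
        conflicts = set()
        for name, df in sections.items():
            for col in ("sequence_id", "protein_id"):
                if col in df.columns:
                    conflicts |= set(df[col]) - known_ids
        if conflicts:
            raise ValueError(
                "unknown sequence ids in report tables: " + ", ".join(sorted(map(str, conflicts)))
            )
    provenance = {
        "tool_version": __version__,
        "config_hash": _digest(sorted((config or {}).items())),
        "seed": str(seed) if seed is not None else "",
        "section_digests": json.dumps(
            {name: _digest(df.to_csv(index=False)) for name, df in sorted(sections.items())},
            sort_keys=True,
        ),
    }
    return CohortReport(sections=dict(sections), provenance=provenance)
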