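"""Table schemas, validated readers/writers and coordinate conventions.

External tables are tab-separated with 1-based inclusive coordinates (VCF
convention); internal interval arithmetic is 0-based half-open.  Conversion
happens only at this boundary.  Each registered schema lists required columns
and their types; unknown columns pass through with a warning, missing
required columns are an error naming the column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

logger = logging.getLogger("l1mosaic")

#: registered table schemas: name -> {column: dtype}
SCHEMAS: dict[str, dict[str, str]] = {
    "events": {
        "sample_id": "str",
        "chrom": "str",
        "target_pos": "int",
        "strand": "str",
        "insertion_class": "str",
        "polyA_len": "int",
        "tsd_len": "int",
        "supporting_pairs": "int",
        "reference_pairs": "int",
    },
    "variants": {
        "chrom": "str",
        "pos": "int",
        "ref": "str",
        "alt": "str",
        "sample": "str",
        "depth": "int",
        "var_reads": "int",
    },
    "methylation": {
        "clone": "str",
        "source": "str",
        "rel_pos": "int",
        "meth": "int",
        "unmeth": "int",
    },
    "registry": {
        "source_id": "str",
        "chrom": "str",
        "start": "int",
        "end": "int",
        "strand": "str",
    },
    "panel": {},  # sources x individuals matrix; validated by shape
}

_CASTERS = {"str": str, "int": "int64", "float": "float64"}


class SchemaError(ValueError):
    pass


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV against a registered schema.

    Malformed rows (uncastable values) are rejected with their line numbers;
    the error message names the offending column.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; registered: {sorted(SCHEMAS)}")
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in table.columns if c not in required]
    if extra and required:
        logger.warning("%s: unknown columns passed through: %s", path, ", ".join(extra))
    for col, kind in required.items():
        if kind == "str":
            continue
        try:
            table[col] = pd.to_numeric(table[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(table[col], errors="coerce").isna()
            lines = [str(i + 2) for i in table.index[bad][:5]]  # +2: header + 1-based
            raise SchemaError(
                f"{path}: column {col!r} not {kind} at line(s) {', '.join(lines)}"
            )
        table[col] = table[col].astype(_CASTERS[kind])
    return table


def write_table(table: pd.DataFrame, path: str | Path, schema: Optional[str] = None) -> None:
    """Write a TSV, validating against a schema when given."""
    if schema is not None:
        required = SCHEMAS.get(schema, {})
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise SchemaError(f"cannot write {schema!r}: missing {', '.join(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def to_internal(pos_1based: int) -> int:
    """1-based inclusive table coordinate -> 0-based half-open start."""
    return pos_1based - 1


def to_external(pos_0based: int) -> int:
    """0-based internal coordinate -> 1-based table coordinate."""
    return pos_0based + 1


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: thresholds with their provenance, echoed by `config dump`
THRESHOLD_PROVENANCE = {
    "panel_vaf_max": (0.01, "stated"),
    "clip_indel_max": (0.70, "stated"),
    "mismatch_max": (3, "stated"),
    "min_depth": (5, "stated"),
    "min_max_vaf": (0.25, "stated"),
    "presence_vaf": (0.1, "stated"),
    "min_support_fraction": (0.10, "stated"),
    "transduction_window_bp": (15000, "stated"),
    "paf_presence_threshold": (0.15, "stated"),
    "cpg_hetero_min": (0.25, "stated"),
    "cpg_meth_min": (0.75, "stated"),
    "scoring_window": ((1, 250), "stated"),
    "epigenotype_open_max": (2.5, "artifact-chosen"),
    "epigenotype_closed_min": (7.5, "artifact-chosen"),
    "gastrulation_window": ((17.0, 65.0), "stated"),
    "cancer_clonal_ccf": (0.7, "stated"),
    "sliding_window_bp": (10_000_000, "stated"),
    "sliding_step_bp": (5_000_000, "stated"),
}


@dataclass
class RunConfig:
    """Paths, seed and thresholds for a pipeline run."""

    out_dir: Path = Path("l1mosaic_out")
    seed: int = 0
    verbosity: str = "info"
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate",
            "calls",
            "phylogeny",
            "rates",
            "sources",
            "methylation",
            "enrichment",
        ]
    )
    simulation: dict = field(default_factory=dict)
    thresholds: dict = field(
        default_factory=lambda: {k: v for k, (v, _) in THRESHOLD_PROVENANCE.items()}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "out_dir" in raw:
            cfg.out_dir = Path(raw["out_dir"])
        for key in ("seed", "verbosity", "stages", "simulation"):
            if key in raw:
                setattr(cfg, key, raw[key])
        cfg.thresholds.update(raw.get("thresholds", {}))
        return cfg

    def dump(self) -> dict:
        """Machine-readable config echo with per-threshold provenance."""
        return {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "stages": self.stages,
            "simulation": self.simulation,
            "thresholds": {
                key: {
                    "value": self.thresholds[key],
                    "provenance": THRESHOLD_PROVENANCE.get(key, (None, "user"))[1],
                }
                for key in self.thresholds
            },
        }


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(value):
    import numpy as np

    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    if isinstance(value, Path):
        return str(value)
    if isinstance(value, (set, frozenset, tuple)):
        return sorted(value) if isinstance(value, (set, frozenset)) else list(value)
    raise TypeError(f"not JSON serializable: {type(value)}")
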