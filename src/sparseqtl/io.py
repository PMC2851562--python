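"""Delimited-text I/O, configuration and provenance.

File dialects (all TSV with a header row; lines starting with '#' are
provenance/comment lines):

* genotypes: first column ``strain``, one column per marker; codes may be
  the founder letters A/B, numeric values in [-0.5, 0.5], or a missing
  token (NA, -, ?).
* marker map: columns ``marker``, ``chr``, ``cm``, ``mbp``.
* expression (one file per tissue): first column ``strain``, one column
  per probe.  Strain rows are aligned across tissues by label.
"""

from __future__ import annotations

import hashlib
import sys
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import FOUNDER_A, FOUNDER_B, ExpressionPanel, GenotypePanel, MarkerMap

__all__ = [
    "read_marker_map",
    "read_genotypes",
    "read_expression_tables",
    "expression_panel_for_probe",
    "write_genotypes",
    "write_marker_map",
    "write_expression",
    "write_table",
    "RunConfig",
]

MISSING_TOKENS = {"NA", "-", "?", "", "NAN"}


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_marker_map(path) -> MarkerMap:
    df = _read_tsv(path)
    for col in ("cm", "mbp"):
        df[col] = df[col].astype(float)
    return MarkerMap(df)


def _decode_genotype(val: str) -> float:
    v = str(val).strip().upper()
    if v in MISSING_TOKENS:
        return np.nan
    if v == "A":
        return FOUNDER_A
    if v == "B":
        return FOUNDER_B
    return float(val)


def read_genotypes(path, marker_map: MarkerMap) -> GenotypePanel:
    df = _read_tsv(path)
    if df.columns[0] != "strain":
        raise ValueError("genotype file must start with a 'strain' column")
    strains = df["strain"].tolist()
    markers = list(df.columns[1:])
    expected = list(marker_map.names)
    if sorted(markers) != sorted(expected):
        missing = set(expected) - set(markers)
        extra = set(markers) - set(expected)
        raise ValueError(
            f"genotype markers disagree with map (missing {sorted(missing)[:5]}, "
            f"unmapped {sorted(extra)[:5]})"
        )
    codes = np.array(
        [[_decode_genotype(v) for v in df[m]] for m in expected], dtype=float
    ).T
    return GenotypePanel(codes=codes, marker_map=marker_map, strain_ids=strains)


def read_expression_tables(paths: dict[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Read per-tissue expression tables and align strain rows by label.

    A tissue whose strain order differs from the first file is realigned
    with a warning; a missing strain is a hard error.
    """
    tables = {}
    ref_order = None
    for tissue, path in paths.items():
        df = _read_tsv(path)
        if df.columns[0] != "strain":
            raise ValueError(f"{path}: expression file must start with 'strain'")
        df = df.set_index("strain").astype(float)
        if ref_order is None:
            ref_order = list(df.index)
        else:
            if list(df.index) != ref_order:
                if set(df.index) != set(ref_order):
                    raise ValueError(f"{path}: strain set differs across tissues")
                warnings.warn(
                    f"{path}: strain order differs; realigning by label", UserWarning
                )
                df = df.loc[ref_order]
        tables[tissue] = df
    return tables


def expression_panel_for_probe(
    tables: dict[str, pd.DataFrame],
    probe: str,
    probe_chr: str | None = None,
    probe_mbp: float | None = None,
) -> ExpressionPanel:
    """Assemble the strains x tissues panel of one probe from per-tissue
    tables (columns ordered as the tables dict)."""
    tissues = list(tables)
    vals = np.column_stack([tables[t][probe].to_numpy() for t in tissues])
    strains = list(next(iter(tables.values())).index)
    return ExpressionPanel(
        values=vals,
        strain_ids=strains,
        tissue_ids=tissues,
        probe_id=probe,
        probe_chr=probe_chr,
        probe_mbp=probe_mbp,
    )


# ---------------------------------------------------------------------------
# writers


def _provenance(command: str | None, seed=None, config_hash=None) -> str:
    parts = [f"# sparseqtl"]
    if command:
        parts.append(f"command={command}")
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config_hash={config_hash}")
    return " ".join(parts)


def write_table(df: pd.DataFrame, path, command=None, seed=None, config_hash=None, index=False):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(command, seed, config_hash) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def write_marker_map(mm: MarkerMap, path, **prov):
    write_table(mm.table, path, **prov)


def write_genotypes(X: GenotypePanel, path, **prov):
    df = pd.DataFrame(X.codes, columns=X.marker_map.names)
    df.insert(0, "strain", X.strain_ids)
    write_table(df, path, **prov)


def write_expression(panel_values: np.ndarray, strains, probes, path, **prov):
    df = pd.DataFrame(np.asarray(panel_values), columns=list(probes))
    df.insert(0, "strain", list(strains))
    write_table(df, path, **prov)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Structured run configuration (YAML-serialisable).

    Sections mirror the pipeline stages; unknown keys are rejected on load
    so a typo never silently falls back to a default.
    """

    sampler: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)
    postprocess: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    _SECTION_KEYS = {
        "sampler": {
            "n_chains", "n_sweeps", "burn_in", "move_probs", "crossover_prob",
            "exchange_prob", "crossover_kind", "target_exchange_rate",
            "adapt_window", "adapt_step", "initial_ladder_ratio", "initial_tau",
            "stepwise_f_enter", "stepwise_max_per_tissue", "seed",
        },
        "model": {"delta", "k_scale", "e_size", "v_size", "max_model_size", "tau_grid_size"},
        "calibration": {"fdr_level", "n_shuffles"},
        "postprocess": {"window_cm", "distinct_cm", "window_mbp", "kappa", "n_draws"},
        "paths": {"genotypes", "marker_map", "expression", "output_dir"},
    }

    def __post_init__(self):
        for section, allowed in self._SECTION_KEYS.items():
            got = getattr(self, section)
            unknown = set(got) - allowed
            if unknown:
                raise ValueError(f"unknown keys in config section {section}: {sorted(unknown)}")
        self._validate_bounds()

    def _validate_bounds(self):
        s = self.sampler
        if "n_sweeps" in s and "burn_in" in s and not (0 < s["burn_in"] < s["n_sweeps"]):
            raise ValueError("require 0 < burn_in < n_sweeps")
        c = self.calibration
        if "fdr_level" in c and not (0 < c["fdr_level"] < 1):
            raise ValueError("fdr_level must be in (0, 1)")
        m = self.model
        if "delta" in m and m["delta"] <= 2:
            raise ValueError("delta must exceed 2")

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls._SECTION_KEYS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)

    def dump(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def log(self, command: str, seed=None, stream=sys.stderr):
        print(
            f"[sparseqtl] {command} seed={seed} config={self.digest()} "
            f"python={sys.version.split()[0]} numpy={np.__version__}",
            file=stream,
        )
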