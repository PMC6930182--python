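"""Tab-separated readers and writers for populations, scans, curves and networks.

All output files start with ``#``-prefixed metadata lines (tool version,
seed, config hash) and are plain UTF-8 TSV with ``NA`` for missing
values, so they diff cleanly and open in any spreadsheet.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .funmap import (
    CrossType,
    EffectCurve,
    INTERCROSS_CODES,
    MISSING_CODES,
    MappingPopulation,
    MarkerRecord,
    ScanResult,
    TESTCROSS_CODES,
)

__all__ = [
    "RunConfig",
    "config_hash",
    "write_population",
    "read_population",
    "write_scan_results",
    "write_manhattan",
    "write_curves",
    "read_curves",
]

_VALID_CODES = set(TESTCROSS_CODES) | set(INTERCROSS_CODES)


@dataclass
class RunConfig:
    """One flat configuration record driving a pipeline run.

    Loaded from a YAML mapping; unknown keys are rejected so typos fail
    loudly.  ``validate`` checks value ranges and that referenced input
    paths exist.
    """

    directions: list[str] = field(default_factory=lambda: ["pi"])
    alpha: float = 0.05
    min_count: int = 10
    rho_init: float = 0.3
    basis_order: int = 2
    lam: float | None = None
    n_lambda: int = 20
    rk4_substeps: int = 4
    replicates: int = 100
    sim_rho: float = 0.5
    seed: int = 0
    phenotype_path: str | None = None
    marker_path: str | None = None
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if any(d not in ("pi", "mi") for d in self.directions):
            raise ValueError(f"directions must be 'pi'/'mi', got {self.directions}")
        if self.basis_order < 1 or self.rk4_substeps < 1:
            raise ValueError("basis_order and rk4_substeps must be >= 1")
        for p in (self.phenotype_path, self.marker_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"referenced input does not exist: {p}")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header(seed=None, config: dict | None = None) -> str:
    parts = [f"# allonet v{__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if config is not None:
        parts.append(f"# config_hash={config_hash(config)}")
    return "\n".join(parts) + "\n"


def _write_tsv(df: pd.DataFrame, path, seed=None, config=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(seed=seed, config=config))
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def write_population(pop: MappingPopulation, phenotype_path, marker_path,
                     seed=None, config=None) -> None:
    """Write the phenotype table (one row per individual x trait) and marker table."""
    tcols = [f"t{j + 1}" for j in range(pop.T)]
    rows = []
    for trait, mat in (("height", pop.heights), ("diameter", pop.diameters)):
        for i, ind in enumerate(pop.ids):
            rows.append({"id": ind, "trait": trait,
                         **{c: mat[i, j] for j, c in enumerate(tcols)}})
    _write_tsv(pd.DataFrame(rows), phenotype_path, seed=seed, config=config)

    mrows = []
    for m in pop.markers:
        mrows.append({"id": m.id, "chrom": m.chrom, "pos": m.pos,
                      "cross_type": m.cross_type.value,
                      **{f"g_{ind}": (c if c not in MISSING_CODES else "NA")
                         for ind, c in zip(pop.ids, m.codes)}})
    _write_tsv(pd.DataFrame(mrows), marker_path, seed=seed, config=config)


def read_population(phenotype_path, marker_path, family_id: str | None = None) -> MappingPopulation:
    """Load and validate a population from the phenotype/marker TSV pair.

    Errors are specific: duplicated individual ids, marker genotype
    columns that do not match the phenotype individual set, and unknown
    genotype codes each raise with the offending name.
    """
    ph = pd.read_csv(phenotype_path, sep="\t", comment="#", dtype={"id": str})
    if not {"id", "trait"} <= set(ph.columns):
        raise ValueError("phenotype file must have 'id' and 'trait' columns")
    tcols = [c for c in ph.columns if c.startswith("t") and c[1:].isdigit()]
    tcols.sort(key=lambda c: int(c[1:]))
    mats = {}
    ids = None
    for trait in ("height", "diameter"):
        sub = ph[ph["trait"] == trait]
        if sub["id"].duplicated().any():
            dup = sub["id"][sub["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicated individual id {dup!r} for trait {trait}")
        sub = sub.set_index("id")
        if ids is None:
            ids = list(sub.index)
        elif set(sub.index) != set(ids):
            raise ValueError("height and diameter rows cover different individuals")
        mats[trait] = sub.loc[ids, tcols].to_numpy(dtype=float)

    mk = pd.read_csv(marker_path, sep="\t", comment="#", dtype=str)
    gcols = [c for c in mk.columns if c.startswith("g_")]
    file_inds = [c[2:] for c in gcols]
    if set(file_inds) != set(ids):
        missing = sorted(set(ids) - set(file_inds))[:3]
        extra = sorted(set(file_inds) - set(ids))[:3]
        raise ValueError(
            f"marker genotype columns mismatch phenotype individuals "
            f"(missing {missing}, unexpected {extra})"
        )
    order = [f"g_{ind}" for ind in ids]
    markers = []
    for _, row in mk.iterrows():
        codes = []
        for col in order:
            c = row[col]
            c = "" if (pd.isna(c) or str(c).strip() in ("NA", "")) else str(c).strip().lower()
            if c and c not in _VALID_CODES:
                raise ValueError(
                    f"unknown genotype code {c!r} at marker {row['id']!r}, column {col!r}"
                )
            codes.append(c)
        markers.append(MarkerRecord(
            id=str(row["id"]), chrom=str(row["chrom"]), pos=int(row["pos"]),
            cross_type=CrossType(row["cross_type"]), codes=codes,
        ))
    pop = MappingPopulation(
        heights=mats["height"], diameters=mats["diameter"], markers=markers,
        family_id=family_id or Path(phenotype_path).stem, ids=ids,
    )
    n_tc = sum(1 for m in markers if m.cross_type == CrossType.TESTCROSS)
    import logging
    logging.getLogger(__name__).info(
        "loaded %d individuals, %d occasions, %d markers (%d testcross, %d intercross)",
        pop.n, pop.T, len(markers), n_tc, len(markers) - n_tc,
    )
    return pop


def _params_columns(r: ScanResult) -> dict:
    out = {}
    if r.alt_fit is not None:
        for j, p in enumerate(r.alt_fit.params_by_group, start=1):
            out[f"a{j}"], out[f"b{j}"], out[f"d{j}"] = p.a, p.b, p.d
        out["rho"] = r.alt_fit.ar1.rho
        out["sigma2"] = r.alt_fit.ar1.sigma2
    return out


def write_scan_results(results: list[ScanResult], path, seed=None, config=None) -> None:
    rows = []
    for r in results:
        rows.append({
            "marker": r.marker.id, "chrom": r.marker.chrom, "pos": r.marker.pos,
            "cross_type": r.marker.cross_type.value, "direction": r.direction.value,
            "LR": r.LR, "df": r.df, "p": r.p,
            "neglog10p": r.neglog10p if not r.skipped else np.nan,
            "significant": r.significant, "skipped": r.skipped,
            "skip_reason": r.skip_reason or "NA", **_params_columns(r),
        })
    _write_tsv(pd.DataFrame(rows), path, seed=seed, config=config)


def write_manhattan(results: list[ScanResult], levels: dict, path,
                    seed=None, config=None) -> None:
    """Manhattan-ready export: chrom, pos, -log10 p, cross type, threshold line."""
    rows = []
    for r in results:
        if r.skipped:
            continue
        level = levels.get(r.marker.cross_type, np.nan)
        rows.append({
            "chrom": r.marker.chrom, "pos": r.marker.pos,
            "neglog10p": r.neglog10p,
            "cross_type": r.marker.cross_type.value,
            "threshold_neglog10": -np.log10(level) if level == level else np.nan,
        })
    _write_tsv(pd.DataFrame(rows), path, seed=seed, config=config)


def write_curves(curves: list[EffectCurve], path, seed=None, config=None) -> None:
    """Long-format export: qtl, component, occasion, predictor_mean, value."""
    rows = []
    for c in curves:
        comps = {"effect": c.values, **c.components}
        for name, vals in comps.items():
            for g, pm, v in zip(c.grid, c.predictor_mean, vals):
                rows.append({"qtl": c.qtl_id, "qtl_class": c.qtl_class,
                             "component": name, "t": g, "predictor_mean": pm,
                             "value": v})
    _write_tsv(pd.DataFrame(rows), path, seed=seed, config=config)


def read_curves(path) -> list[EffectCurve]:
    """Read the 'effect' component of a long-format curve TSV back into curves."""
    df = pd.read_csv(path, sep="\t", comment="#")
    curves = []
    for qtl, sub in df[df["component"] == "effect"].groupby("qtl", sort=False):
        sub = sub.sort_values("t")
        curves.append(EffectCurve(
            qtl_id=str(qtl), qtl_class=str(sub["qtl_class"].iloc[0]),
            grid=sub["t"].to_numpy(float),
            predictor_mean=sub["predictor_mean"].to_numpy(float),
            values=sub["value"].to_numpy(float),
        ))
    return curves
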