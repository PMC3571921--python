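"""Per-condition multi-omic measurement tables and WSLS weights.

Four UTF-8 CSV files describe a chemostat study:

``conditions.csv``
    columns ``condition_id``, ``dilution_rate`` (1/h), ``knockout``
    (reaction id, may be empty).
``fluxes.csv``
    ``condition_id`` plus one column per measured reaction
    (mmol/gDW/h; blank = not measured).
``metabolites.csv`` / ``enzymes.csv``
    ``condition_id`` plus ``<id>_mean`` / ``<id>_sd`` column pairs
    (mM resp. mg protein/gDCW; blank mean = missing measurement).

Weights for the weighted-least-squares objective are inverse measurement
variances; a relative variance floor keeps near-zero replicate variances
from dominating the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class Measurement:
    mean: float
    sd: float


@dataclass
class ConditionRecord:
    condition_id: str
    dilution_rate: float
    knockout: str | None = None
    fluxes: dict[str, float] = field(default_factory=dict)
    metabolites: dict[str, Measurement] = field(default_factory=dict)
    enzymes: dict[str, Measurement] = field(default_factory=dict)

    def __post_init__(self):
        if not self.dilution_rate > 0:
            raise SchemaError(
                f"{self.condition_id}: dilution rate must be > 0")
        for space in (self.metabolites, self.enzymes):
            for key, m in space.items():
                if m.mean < 0 or m.sd < 0 or not math.isfinite(m.mean):
                    raise SchemaError(
                        f"{self.condition_id}/{key}: negative or "
                        f"non-finite mean/sd")


@dataclass
class OmicsDataset:
    conditions: list[ConditionRecord]
    metabolite_ids: list[str]
    enzyme_ids: list[str]

    def __post_init__(self):
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate condition ids: {dup}")
        for c in self.conditions:
            for m in c.metabolites:
                if m not in self.metabolite_ids:
                    raise SchemaError(
                        f"{c.condition_id}: unknown metabolite {m!r}")
            for e in c.enzymes:
                if e not in self.enzyme_ids:
                    raise SchemaError(
                        f"{c.condition_id}: unknown enzyme {e!r}")

    @property
    def condition_ids(self) -> list[str]:
        return [c.condition_id for c in self.conditions]

    def condition(self, cid: str) -> ConditionRecord:
        for c in self.conditions:
            if c.condition_id == cid:
                return c
        raise KeyError(f"unknown condition {cid!r}")

    def subset(self, condition_ids) -> "OmicsDataset":
        keep = set(condition_ids)
        return OmicsDataset(
            [c for c in self.conditions if c.condition_id in keep],
            list(self.metabolite_ids), list(self.enzyme_ids))

    def n_measurements(self) -> dict[str, int]:
        return {
            "metabolites": sum(len(c.metabolites) for c in self.conditions),
            "enzymes": sum(len(c.enzymes) for c in self.conditions),
            "fluxes": sum(len(c.fluxes) for c in self.conditions),
        }


@dataclass
class WeightTable:
    """Inverse-variance weights; zero exactly for missing measurements."""

    W_c: dict[tuple[str, str], float]  # (condition, metabolite) -> 1/mM^2
    W_e: dict[tuple[str, str], float]  # (condition, enzyme)

    def metabolite(self, cid: str, met: str) -> float:
        return self.W_c.get((cid, met), 0.0)

    def enzyme(self, cid: str, enz: str) -> float:
        return self.W_e.get((cid, enz), 0.0)


def compute_weights(ds: OmicsDataset,
                    variance_floor: float = 0.05) -> WeightTable:
    """Inverse-variance weights with a relative floor.

    W = 1 / max(sd^2, (variance_floor * mean)^2) for measured entries and
    0 for missing ones.  When a species' sd is absent in some condition the
    species' mean sd across conditions stands in (one shared
    replicate-derived variance per species), before the floor applies.
    """
    if variance_floor < 0:
        raise ValueError("variance_floor must be >= 0")

    def _weights(space: str) -> dict[tuple[str, str], float]:
        shared_sd: dict[str, float] = {}
        per_species: dict[str, list[float]] = {}
        for c in ds.conditions:
            for key, m in getattr(c, space).items():
                if not math.isnan(m.sd):
                    per_species.setdefault(key, []).append(m.sd)
        for key, sds in per_species.items():
            shared_sd[key] = float(np.mean(sds))
        out = {}
        for c in ds.conditions:
            for key, m in getattr(c, space).items():
                sd = m.sd if not math.isnan(m.sd) else shared_sd.get(
                    key, float("nan"))
                if math.isnan(sd):
                    sd = 0.0
                var = max(sd ** 2, (variance_floor * m.mean) ** 2)
                if var == 0:
                    raise ValueError(
                        f"{c.condition_id}/{key}: zero variance with zero "
                        f"floor; supply a variance_floor > 0")
                out[(c.condition_id, key)] = 1.0 / var
        return out

    return WeightTable(W_c=_weights("metabolites"),
                       W_e=_weights("enzymes"))


# --------------------------------------------------------------------------
# CSV reading / writing
# --------------------------------------------------------------------------

def read_omics_tables(flux_path, metabolite_path, enzyme_path,
                      condition_path,
                      known_reactions=None) -> OmicsDataset:
    """Read and validate the four study CSV files."""
    cond = pd.read_csv(condition_path, dtype={"condition_id": str})
    for col in ("condition_id", "dilution_rate"):
        if col not in cond.columns:
            raise SchemaError(f"{condition_path}: missing column {col!r}")
    flux = pd.read_csv(flux_path, dtype={"condition_id": str})
    metab = pd.read_csv(metabolite_path, dtype={"condition_id": str})
    enz = pd.read_csv(enzyme_path, dtype={"condition_id": str})
    for name, df in (("fluxes", flux), ("metabolites", metab),
                     ("enzymes", enz)):
        if "condition_id" not in df.columns:
            raise SchemaError(f"{name} table: missing condition_id column")

    met_ids = _pair_ids(metab, "metabolites")
    enz_ids = _pair_ids(enz, "enzymes")
    flux_rxns = [c for c in flux.columns if c != "condition_id"]
    if known_reactions is not None:
        unknown = sorted(set(flux_rxns) - set(known_reactions))
        if unknown:
            raise SchemaError(
                f"flux table references unknown reactions: {unknown}")

    def _row(df, cid, table):
        sel = df[df["condition_id"] == cid]
        if len(sel) > 1:
            raise SchemaError(f"{table}: duplicate rows for {cid!r}")
        return sel.iloc[0] if len(sel) else None

    records = []
    for _, crow in cond.iterrows():
        cid = str(crow["condition_id"])
        ko = crow.get("knockout")
        ko = None if (ko is None or (isinstance(ko, float) and
                                     math.isnan(ko)) or ko == "") else ko
        fluxes = {}
        frow = _row(flux, cid, "fluxes")
        if frow is not None:
            for rxn in flux_rxns:
                v = frow[rxn]
                if not pd.isna(v):
                    fluxes[rxn] = float(v)
        records.append(ConditionRecord(
            condition_id=cid,
            dilution_rate=float(crow["dilution_rate"]),
            knockout=ko,
            fluxes=fluxes,
            metabolites=_measurements(_row(metab, cid, "metabolites"),
                                      met_ids, cid),
            enzymes=_measurements(_row(enz, cid, "enzymes"), enz_ids, cid),
        ))
    return OmicsDataset(records, met_ids, enz_ids)


def _pair_ids(df: pd.DataFrame, table: str) -> list[str]:
    ids = []
    for col in df.columns:
        if col.endswith("_mean"):
            base = col[:-5]
            if f"{base}_sd" not in df.columns:
                raise SchemaError(f"{table}: {col} without {base}_sd")
            ids.append(base)
    return ids


def _measurements(row, ids, cid) -> dict[str, Measurement]:
    out = {}
    if row is None:
        return out
    for key in ids:
        mean = row[f"{key}_mean"]
        if pd.isna(mean):
            continue
        sd = row[f"{key}_sd"]
        mean = float(mean)
        sd = float(sd) if not pd.isna(sd) else float("nan")
        if mean < 0:
            raise SchemaError(f"{cid}/{key}: negative mean {mean}")
        if not math.isnan(sd) and sd < 0:
            raise SchemaError(f"{cid}/{key}: negative sd {sd}")
        out[key] = Measurement(mean, sd)
    return out


def write_omics_tables(ds: OmicsDataset, outdir) -> dict[str, str]:
    """Write the four study CSVs; returns the paths written."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    cond = pd.DataFrame(
        {"condition_id": [c.condition_id for c in ds.conditions],
         "dilution_rate": [c.dilution_rate for c in ds.conditions],
         "knockout": [c.knockout or "" for c in ds.conditions]})
    paths["conditions"] = p = os.path.join(outdir, "conditions.csv")
    cond.to_csv(p, index=False)

    rxns = sorted({r for c in ds.conditions for r in c.fluxes})
    flux = pd.DataFrame(
        [{"condition_id": c.condition_id,
          **{r: c.fluxes.get(r, np.nan) for r in rxns}}
         for c in ds.conditions])
    paths["fluxes"] = p = os.path.join(outdir, "fluxes.csv")
    flux.to_csv(p, index=False)

    for space, ids, fname in (("metabolites", ds.metabolite_ids,
                               "metabolites.csv"),
                              ("enzymes", ds.enzyme_ids, "enzymes.csv")):
        rows = []
        for c in ds.conditions:
            row = {"condition_id": c.condition_id}
            data = getattr(c, space)
            for key in ids:
                m = data.get(key)
                row[f"{key}_mean"] = m.mean if m else np.nan
                row[f"{key}_sd"] = m.sd if m else np.nan
            rows.append(row)
        paths[space] = p = os.path.join(outdir, fname)
        pd.DataFrame(rows).to_csv(p, index=False)
    return paths


def completeness_report(ds: OmicsDataset) -> pd.DataFrame:
    """Per-condition measurement counts and missing fractions."""
    rows = []
    for c in ds.conditions:
        n_met = len(ds.metabolite_ids)
        n_enz = len(ds.enzyme_ids)
        rows.append({
            "condition_id": c.condition_id,
            "dilution_rate": c.dilution_rate,
            "knockout": c.knockout or "",
            "n_fluxes": len(c.fluxes),
            "n_metabolites": len(c.metabolites),
            "metabolite_missing_frac":
                1.0 - len(c.metabolites) / n_met if n_met else 0.0,
            "n_enzymes": len(c.enzymes),
            "enzyme_missing_frac":
                1.0 - len(c.enzymes) / n_enz if n_enz else 0.0,
        })
    return pd.DataFrame(rows)
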