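"""Reading and writing models, scenarios and reports.

Supported model formats:

* SBML Level 3 with the FBC package (community standard; read via COBRApy);
* a native JSON dialect with explicit metabolite/reaction lists, per-reaction
  stoichiometry maps, bounds and objective coefficients, and an optional
  ``constraints`` block for general inequalities ``A r <= b`` (which have no
  standard home in SBML-FBC);
* TSV: a stoichiometry matrix whose header row holds the reaction ids and
  whose first column holds the metabolite ids, with an optional separate
  bounds table.

Infinite bounds are encoded as +-1e30 in files (the usual LP-solver
convention) and mapped to true +-inf in memory.  Files always refer to
reactions and metabolites by identifier, never by position.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ModelError, ScenarioError
from .model import FluxScenario, MetabolicModel

__all__ = [
    "load_model",
    "load_scenario",
    "save_model_json",
    "write_scenario_tsv",
    "write_report",
    "read_report",
    "FILE_INF",
]

FILE_INF = 1e30


def _from_file(v: float) -> float:
    if v >= FILE_INF:
        return math.inf
    if v <= -FILE_INF:
        return -math.inf
    return float(v)


def _to_file(v: float) -> float:
    if math.isinf(v):
        return FILE_INF if v > 0 else -FILE_INF
    return float(v)


def load_model(path, format: str | None = None, bounds_path=None) -> MetabolicModel:
    """Load a metabolic model from SBML, native JSON or TSV.

    ``format`` is inferred from the suffix when omitted (.xml/.sbml -> sbml,
    .json -> json, .tsv/.txt -> tsv).  ``bounds_path`` optionally names a TSV
    bounds table (reaction_id, lb, ub) accompanying a TSV stoichiometry.
    """
    path = Path(path)
    if not path.exists():
        raise ModelError(f"model file not found: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {".xml": "sbml", ".sbml": "sbml", ".json": "json", ".tsv": "tsv", ".txt": "tsv"}.get(
            suffix
        )
        if format is None:
            raise ModelError(f"cannot infer model format from suffix {suffix!r}")
    if format == "sbml":
        return _load_sbml(path)
    if format == "json":
        return _load_json(path)
    if format == "tsv":
        return _load_tsv(path, bounds_path)
    raise ModelError(f"unknown model format {format!r}")


def _load_sbml(path: Path) -> MetabolicModel:
    from cobra.io import read_sbml_model  # deferred: cobra import is slow
    from cobra.util.array import create_stoichiometric_matrix

    try:
        cmodel = read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise ModelError(f"SBML parse failure for {path}: {exc}") from exc
    if len(cmodel.reactions) == 0:
        raise ModelError("empty model: SBML file declares no reactions")
    N = create_stoichiometric_matrix(cmodel)
    lb = np.array([_from_file(r.lower_bound) for r in cmodel.reactions])
    ub = np.array([_from_file(r.upper_bound) for r in cmodel.reactions])
    obj = np.array([r.objective_coefficient for r in cmodel.reactions])
    return MetabolicModel(
        reaction_ids=[r.id for r in cmodel.reactions],
        metabolite_ids=[m.id for m in cmodel.metabolites],
        N=N,
        lb=lb,
        ub=ub,
        objective_c=obj if np.any(obj) else None,
    )


def _load_json(path: Path) -> MetabolicModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"JSON parse failure for {path}: {exc}") from exc
    try:
        met_ids = [m["id"] for m in data["metabolites"]]
        reactions = data["reactions"]
    except (KeyError, TypeError) as exc:
        raise ModelError(f"malformed model JSON {path}: {exc}") from exc
    if not reactions:
        raise ModelError("empty model: no reactions in JSON file")
    rxn_ids = [r["id"] for r in reactions]
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    N = np.zeros((len(met_ids), len(rxn_ids)))
    lb = np.empty(len(rxn_ids))
    ub = np.empty(len(rxn_ids))
    obj = np.zeros(len(rxn_ids))
    for j, r in enumerate(reactions):
        for mid, coef in r.get("stoichiometry", {}).items():
            if mid not in met_index:
                raise ModelError(f"reaction {r['id']!r} references unknown metabolite {mid!r}")
            N[met_index[mid], j] = float(coef)
        lb[j] = _from_file(float(r.get("lb", -FILE_INF)))
        ub[j] = _from_file(float(r.get("ub", FILE_INF)))
        obj[j] = float(r.get("objective", 0.0))
    A = b = None
    if "constraints" in data and data["constraints"]:
        cons = data["constraints"]
        rows = cons.get("rows", [])
        b = np.array([float(v) for v in cons.get("b", [])])
        if len(rows) != len(b):
            raise ModelError("constraints block: number of rows does not match length of b")
        rxn_index = {rid: j for j, rid in enumerate(rxn_ids)}
        A = np.zeros((len(rows), len(rxn_ids)))
        for i, row in enumerate(rows):
            for rid, coef in row.items():
                if rid not in rxn_index:
                    raise ModelError(f"constraint row {i} references unknown reaction {rid!r}")
                A[i, rxn_index[rid]] = float(coef)
    return MetabolicModel(
        reaction_ids=rxn_ids,
        metabolite_ids=met_ids,
        N=N,
        lb=lb,
        ub=ub,
        A=A,
        b=b,
        objective_c=obj if np.any(obj) else None,
    )


def _load_tsv(path: Path, bounds_path=None) -> MetabolicModel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ModelError("empty model: TSV stoichiometry declares no reactions")
    rxn_ids = [str(c) for c in df.columns]
    met_ids = [str(i) for i in df.index]
    N = df.to_numpy(dtype=float)
    lb = np.full(len(rxn_ids), -math.inf)
    ub = np.full(len(rxn_ids), math.inf)
    if bounds_path is not None:
        bdf = pd.read_csv(bounds_path, sep="\t")
        required = {"reaction_id", "lb", "ub"}
        if not required.issubset(bdf.columns):
            raise ModelError(f"bounds table must have columns {sorted(required)}")
        rxn_index = {rid: j for j, rid in enumerate(rxn_ids)}
        for _, row in bdf.iterrows():
            rid = str(row["reaction_id"])
            if rid not in rxn_index:
                raise ModelError(
                    f"dimension mismatch: bounds table reaction {rid!r} not in the "
                    "declared reaction list"
                )
            j = rxn_index[rid]
            lb[j] = _from_file(float(row["lb"]))
            ub[j] = _from_file(float(row["ub"]))
    return MetabolicModel(reaction_ids=rxn_ids, metabolite_ids=met_ids, N=N, lb=lb, ub=ub)


# ---------------------------------------------------------------------------
# scenarios


def load_scenario(path, model: MetabolicModel) -> FluxScenario:
    """Load a flux scenario (TSV: reaction_id, value[, variance]; or JSON).

    Reactions whose model bounds satisfy lb = ub are additionally imported
    into the fixed set (fixed rates belong in the scenario, not in the
    bounds).  A conflict between such a clamp and an explicit scenario value
    is an error, never a silent override.
    """
    path = Path(path)
    if not path.exists():
        raise ScenarioError(f"scenario file not found: {path}")
    fixed: dict[str, float] = {}
    variances: dict[str, float] = {}
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        fixed = {str(k): float(v) for k, v in data.get("fixed", {}).items()}
        variances = {str(k): float(v) for k, v in data.get("variances", {}).items()}
    elif path.stat().st_size:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[0] and isinstance(df.iloc[0, 1], str):
            df = df.iloc[1:]  # tolerate a header row
        for _, row in df.iterrows():
            rid = str(row[0])
            fixed[rid] = float(row[1])
            if df.shape[1] > 2 and not pd.isna(row[2]):
                variances[rid] = float(row[2])
    for rid in fixed:
        model.reaction_index(rid)  # raises ScenarioError for unknown ids

    # auto-import clamped reactions (lb = ub)
    for j, rid in enumerate(model.reaction_ids):
        if model.lb[j] == model.ub[j] and np.isfinite(model.lb[j]):
            if rid in fixed and fixed[rid] != model.lb[j]:
                raise ScenarioError(
                    f"reaction {rid!r} is clamped to {model.lb[j]} by its bounds but the "
                    f"scenario fixes it at {fixed[rid]}"
                )
            fixed.setdefault(rid, float(model.lb[j]))
    return FluxScenario(fixed=fixed, variances=variances or None)


def write_scenario_tsv(scenario: FluxScenario, path) -> None:
    lines = []
    for rid, f in scenario.fixed.items():
        var = (scenario.variances or {}).get(rid)
        if var is None:
            lines.append(f"{rid}\t{f!r}")
        else:
            lines.append(f"{rid}\t{f!r}\t{var!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_model_json(model: MetabolicModel, path) -> None:
    """Serialize to the native JSON dialect (round-trips with load_model)."""
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        stoich = {
            model.metabolite_ids[i]: model.N[i, j]
            for i in range(model.n_metabolites)
            if model.N[i, j] != 0.0
        }
        entry = {
            "id": rid,
            "stoichiometry": stoich,
            "lb": _to_file(model.lb[j]),
            "ub": _to_file(model.ub[j]),
        }
        if model.objective_c is not None and model.objective_c[j] != 0.0:
            entry["objective"] = model.objective_c[j]
        reactions.append(entry)
    data: dict = {
        "metabolites": [{"id": mid} for mid in model.metabolite_ids],
        "reactions": reactions,
    }
    if model.A is not None:
        rows = []
        for i in range(model.A.shape[0]):
            rows.append(
                {
                    model.reaction_ids[j]: model.A[i, j]
                    for j in range(model.n_reactions)
                    if model.A[i, j] != 0.0
                }
            )
        data["constraints"] = {"rows": rows, "b": [float(v) for v in model.b]}
    Path(path).write_text(json.dumps(data, indent=1))


# ---------------------------------------------------------------------------
# reports


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return [_jsonable(x) for x in v.tolist()]
    if isinstance(v, (np.floating, float)):
        v = float(v)
        return None if math.isnan(v) else (_to_file(v) if math.isinf(v) else v)
    if isinstance(v, (np.integer,)):
        return int(v)
    return v


def report_dict(diagnosis=None, corrections=None, ranges=None) -> dict:
    """Assemble a serializable report from analysis results.

    Corrections are reported uniformly as (corrected - given), regardless of
    the engine's internal sign convention.
    """
    report: dict = {}
    if diagnosis is not None:
        report["diagnosis"] = {
            "determinacy": diagnosis.determinacy,
            "redundancy": diagnosis.redundancy,
            "consistency": diagnosis.consistency,
            "rank_N": diagnosis.rank_N,
            "rank_NU": diagnosis.rank_NU,
            "conservation_relations": diagnosis.c,
            "dof": diagnosis.dof,
            "degR": diagnosis.degR,
            "redundant_rate_ids": list(diagnosis.redundant_rate_ids),
            "determined_unknowns": list(diagnosis.determined_unknowns),
            "residual_inf_norm": _jsonable(
                float(np.abs(diagnosis.residual).max(initial=0.0))
            ),
        }
    if corrections is not None:
        corr = corrections.corrections()
        already = corrections.status == "optimal" and all(
            abs(v) <= 1e-12 for v in corr.values()
        )
        report["corrections"] = {
            "method": corrections.method,
            "status": corrections.status,
            "objective_value": _jsonable(corrections.objective_value),
            "unique": corrections.unique,
            "already_feasible": already,
            "corrections": {rid: _jsonable(v) for rid, v in corr.items()},
            "corrected_values": {
                rid: _jsonable(v) for rid, v in corrections.corrected_values.items()
            },
        }
        if corrections.constraint_slacks:
            report["corrections"]["constraint_slacks"] = _jsonable_tree(
                corrections.constraint_slacks
            )
    if ranges is not None:
        report["fva"] = {
            "det_tol": ranges.det_tol,
            "ranges": {
                rid: [_jsonable(lo), _jsonable(hi)] for rid, (lo, hi) in ranges.ranges.items()
            },
            "determined": {rid: bool(f) for rid, f in ranges.determined.items()},
        }
    return report


def _jsonable_tree(obj):
    if isinstance(obj, dict):
        return {k: _jsonable_tree(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable_tree(v) for v in obj]
    return _jsonable(obj)


def write_report(diagnosis=None, corrections=None, ranges=None, path=None, format="json") -> dict:
    """Write a report of any combination of results; returns the report dict."""
    report = report_dict(diagnosis, corrections, ranges)
    if path is None:
        return report
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report, indent=1, sort_keys=True))
    elif format == "tsv":
        lines = []
        for section, content in report.items():
            for key, value in content.items():
                lines.append(f"{section}\t{key}\t{json.dumps(value, sort_keys=True)}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return report


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
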