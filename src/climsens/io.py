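"""Study-configuration files: YAML study descriptions + CSV driver series.

A study lives in one YAML file naming the species, taxon, life-cycle
structure, vital-rate regressions (family/link, terms, coefficients,
uncertainty) and populations; each population points at a CSV of driver
observations (column ``time`` plus one column per driver).  The synthetic
generator emits exactly this format, so synthetic and real archives are
consumed identically.  Validation happens at load and names the offending
key in every error message.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .study import (
    CovariateTerm,
    Driver,
    Population,
    SpeciesStudy,
    Uncertainty,
    VitalRateModel,
)


def _py(obj):
    """Convert numpy scalars/arrays to plain Python for stable YAML dumps."""
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_py(x) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {k: _py(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_py(x) for x in obj]
    return obj


def _term_to_obj(term: CovariateTerm):
    if term.is_intercept:
        return "intercept"
    key = "state" if term.is_state else "driver"
    obj = {key: term.driver_or_state}
    if term.transformation != "identity":
        obj["transformation"] = term.transformation
    if term.interaction_with:
        obj["interaction_with"] = [_term_to_obj(t) for t in term.interaction_with]
    return obj


def _term_from_obj(obj, where: str) -> CovariateTerm:
    if obj == "intercept":
        return CovariateTerm()
    if not isinstance(obj, dict):
        raise ConfigError(f"{where}: term must be 'intercept' or a mapping")
    if ("driver" in obj) == ("state" in obj):
        raise ConfigError(f"{where}: term needs exactly one of 'driver'/'state'")
    inter = tuple(
        _term_from_obj(t, where) for t in obj.get("interaction_with", [])
    )
    return CovariateTerm(
        driver_or_state=obj.get("driver", obj.get("state")),
        is_state="state" in obj,
        transformation=obj.get("transformation", "identity"),
        interaction_with=inter,
    )


def save_study(study: SpeciesStudy, out_dir) -> Path:
    """Write <species>.yaml plus one driver CSV per population; returns the
    YAML path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pops = []
    for pop in study.populations:
        csv_name = f"{study.species}_{pop.name}_drivers.csv"
        cols = {"time": _py(pop.drivers[0].times)}
        for d in pop.drivers:
            cols[d.name] = _py(d.values)
        pd.DataFrame(cols).to_csv(out_dir / csv_name, index=False)
        pops.append({"name": pop.name, "driver_csv": csv_name})
    doc = {
        "species": study.species,
        "taxon_group": study.taxon_group,
        "age_at_sexual_maturity": _py(study.age_at_sexual_maturity),
        "model_kind": study.model_kind,
        "structure": _py(study.structure),
        "year_effects_shared": study.year_effects_shared,
        "drivers": [
            {"name": d.name, "category": d.category}
            for d in study.populations[0].drivers
        ],
        "populations": pops,
        "vital_rates": [
            {
                "name": m.name,
                "rate_class": m.rate_class,
                "family_link": m.family_link,
                "terms": [_term_to_obj(t) for t in m.terms],
                "coefficients": _py(m.coefficients),
                "uncertainty": (
                    {"kind": m.uncertainty.kind}
                    if m.uncertainty.kind == "none"
                    else {"kind": m.uncertainty.kind, "values": _py(m.uncertainty.values)}
                ),
                **(
                    {"year_effect": _py(m.year_effect)}
                    if m.year_effect
                    else {}
                ),
                **(
                    {"applicable_domain": _py(m.applicable_domain)}
                    if m.applicable_domain is not None
                    else {}
                ),
            }
            for m in study.vital_rate_models
        ],
    }
    if study.matrix_map is not None:
        doc["matrix_map"] = _py(study.matrix_map)
    if study.kernel_map is not None:
        doc["kernel_map"] = _py(study.kernel_map)
    path = out_dir / f"{study.species}.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=None)
    return path


def _require(doc: dict, key: str, where: str):
    if key not in doc:
        raise ConfigError(f"{where}: missing required key {key!r}")
    return doc[key]


def load_study(path) -> SpeciesStudy:
    """Load and validate one study YAML; driver CSVs are resolved relative
    to the YAML file.  All domain invariants are enforced at load."""
    path = Path(path)
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: study file must be a mapping")
    where = str(path)
    categories = {
        d["name"]: d["category"]
        for d in _require(doc, "drivers", where)
    }
    populations = []
    for pdoc in _require(doc, "populations", where):
        csv_path = path.parent / _require(pdoc, "driver_csv", f"{where}:populations")
        if not csv_path.exists():
            raise ConfigError(f"{where}: driver CSV not found: {csv_path}")
        table = pd.read_csv(csv_path, float_precision="round_trip")
        if "time" not in table.columns:
            raise ConfigError(f"{csv_path}: missing 'time' column")
        drivers = []
        for name, cat in categories.items():
            if name not in table.columns:
                raise ConfigError(
                    f"{csv_path}: missing column for driver {name!r}"
                )
            drivers.append(
                Driver(name, cat, table["time"].to_numpy(), table[name].to_numpy(float))
            )
        populations.append(Population(name=pdoc["name"], drivers=drivers))

    models = []
    for mdoc in _require(doc, "vital_rates", where):
        mwhere = f"{where}:vital_rates[{mdoc.get('name', '?')}]"
        unc_doc = mdoc.get("uncertainty", {"kind": "none"})
        uncertainty = Uncertainty(
            kind=unc_doc.get("kind", "none"),
            values=np.asarray(unc_doc["values"], float) if "values" in unc_doc else None,
        )
        models.append(
            VitalRateModel(
                name=_require(mdoc, "name", mwhere),
                rate_class=_require(mdoc, "rate_class", mwhere),
                family_link=_require(mdoc, "family_link", mwhere),
                terms=[_term_from_obj(t, mwhere) for t in _require(mdoc, "terms", mwhere)],
                coefficients=np.asarray(_require(mdoc, "coefficients", mwhere), float),
                uncertainty=uncertainty,
                year_effect=mdoc.get("year_effect"),
                applicable_domain=mdoc.get("applicable_domain"),
            )
        )
    return SpeciesStudy(
        species=_require(doc, "species", where),
        taxon_group=_require(doc, "taxon_group", where),
        age_at_sexual_maturity=float(_require(doc, "age_at_sexual_maturity", where)),
        model_kind=_require(doc, "model_kind", where),
        structure=_require(doc, "structure", where),
        vital_rate_models=models,
        populations=populations,
        matrix_map=doc.get("matrix_map"),
        kernel_map=doc.get("kernel_map"),
        year_effects_shared=bool(doc.get("year_effects_shared", False)),
    )


def load_study_dir(directory) -> list[SpeciesStudy]:
    """Load every *.yaml study in a directory (sorted by filename)."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.yaml"))
    if not paths:
        raise ConfigError(f"no study files (*.yaml) in {directory}")
    return [load_study(p) for p in paths]
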