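"""Bundle serialisation: a directory of CSV tables plus JSON parameter files.

One CSV per table, one row per stratum, documented headers; `params.json`
carries the scalar parameters and `manifest.json` the seed and the true
generating parameters (for test oracles). Floats survive the round trip
exactly (write -> read -> identical bundle).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .bmi_model import SDMeanRelation
from .demand import ElasticityMatrix
from .errors import StructuralError
from .lifetable import CostInputs
from .pif import RRSpec
from .synthetic_data import InputBundle

_TABLES = {
    "consumption": ["age_group", "sex", "beverage"],
    "bmi": ["age_group", "sex"],
    "heights": ["age_group", "sex"],
    "epi": ["age_group", "sex"],
    "rr": ["age_group", "sex"],
    "elasticities": ["beverage"],
    "energy_density": ["beverage"],
}


def write_bundle(bundle: InputBundle, directory: str | Path) -> Path:
    """Write every table of `bundle` under `directory`; returns the path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.consumption.to_csv(d / "consumption.csv")
    bundle.bmi.to_csv(d / "bmi.csv")
    bundle.heights.to_frame().to_csv(d / "heights.csv")
    bundle.epi.to_csv(d / "epi.csv")
    bundle.rr.table.to_csv(d / "rr.csv")
    bundle.elasticities.table.to_csv(d / "elasticities.csv")
    bundle.energy_density.to_csv(d / "energy_density.csv")
    params = {
        "costs": {
            "private_cost": bundle.costs.private_cost,
            "private_share": bundle.costs.private_share,
            "public_ratio": bundle.costs.public_ratio,
        },
        "sd_mean_relation": {
            "slope": bundle.sd_mean_relation.slope,
            "reference_mean": bundle.sd_mean_relation.reference_mean,
            "intercept": bundle.sd_mean_relation.intercept,
        },
        "rr": {
            "tmreb": bundle.rr.tmreb,
            "unit_width": bundle.rr.unit_width,
            "upper": bundle.rr.upper,
        },
        "disability_weight": bundle.disability_weight,
        "k_kj_per_kg": bundle.k_kj_per_kg,
        "k_sd": bundle.k_sd,
    }
    (d / "params.json").write_text(json.dumps(params, indent=2, sort_keys=True))
    (d / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True)
    )
    return d


def _read_table(d: Path, name: str) -> pd.DataFrame:
    path = d / f"{name}.csv"
    if not path.exists():
        raise StructuralError(f"bundle table missing: {path.name}")
    df = pd.read_csv(path)
    missing = [c for c in _TABLES[name] if c not in df.columns]
    if missing:
        raise StructuralError(f"{path.name} lacks index columns {missing}")
    return df.set_index(_TABLES[name])


def read_bundle(directory: str | Path) -> InputBundle:
    """Read a bundle directory written by :func:`write_bundle` (or shaped
    like one by the user)."""
    d = Path(directory)
    if not d.is_dir():
        raise StructuralError(f"bundle directory not found: {d}")
    params_path = d / "params.json"
    if not params_path.exists():
        raise StructuralError("bundle lacks params.json")
    params = json.loads(params_path.read_text())
    manifest_path = d / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}

    heights_df = _read_table(d, "heights")
    if "height_m" not in heights_df.columns:
        raise StructuralError("heights.csv lacks column 'height_m'")

    rel = params.get("sd_mean_relation", {})
    rr_params = params.get("rr", {})
    return InputBundle(
        consumption=_read_table(d, "consumption"),
        bmi=_read_table(d, "bmi"),
        heights=heights_df["height_m"],
        epi=_read_table(d, "epi"),
        rr=RRSpec(
            _read_table(d, "rr"),
            tmreb=rr_params.get("tmreb", 21.0),
            unit_width=rr_params.get("unit_width", 5.0),
            upper=rr_params.get("upper", 80.0),
        ),
        elasticities=ElasticityMatrix(_read_table(d, "elasticities")),
        energy_density=_read_table(d, "energy_density"),
        costs=CostInputs(**params["costs"]),
        sd_mean_relation=SDMeanRelation(
            slope=rel.get("slope", 0.0),
            reference_mean=rel.get("reference_mean"),
            intercept=rel.get("intercept", 0.0),
        ),
        disability_weight=params.get("disability_weight", 0.28),
        k_kj_per_kg=params.get("k_kj_per_kg", 94.0),
        k_sd=params.get("k_sd", 2.96),
        manifest=manifest,
    )
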