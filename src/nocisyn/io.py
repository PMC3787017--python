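"""CSV/JSON readers and writers for all schemas, plus run manifests.

Units are fixed by convention rather than per-cell strings: doses in mg/kg,
times in minutes, potencies in -log10 molar, signals in arbitrary units.

Flinch CSV columns: session, animal_id, arm, drug1, dose1_mg_kg
[, drug2, dose2_mg_kg, ...], bin_start_min, bin_end_min, flinches.
Drug/dose column pairs repeat for mixtures; blanks mean "no drug" (vehicle).

Binding CSV columns: session, animal_id, arm, transporter, time_min, signal.

Compound profile CSV columns: name, pic50_sert, pic50_net, pki_sert,
pki_net, fu_plasma, fu_brain (optional values blank).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import re
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import pandas as pd

from .behavior import FlinchDataset, FlinchRecord, GroupSummary
from .dose_response import DoseResponseFit
from .occupancy import BindingTimeCourse, OccupancyRecord
from .profiles import CompoundProfile
from .synergy import IsobologramResult

__all__ = [
    "read_flinch_csv",
    "write_flinch_csv",
    "read_binding_csv",
    "write_binding_csv",
    "read_compound_csv",
    "to_jsonable",
    "write_json_report",
    "format_fit",
    "format_isobologram",
    "RunManifest",
    "write_manifest",
]

_DRUG_COL = re.compile(r"^drug(\d+)$")


def _row_error(path: Union[str, Path], line: int, msg: str) -> ValueError:
    return ValueError(f"{path}, data row {line}: {msg}")


def read_flinch_csv(path: Union[str, Path]) -> FlinchDataset:
    """Read a flinch-count CSV into a validated :class:`FlinchDataset`.

    Malformed rows are reported with their 1-based data row number.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"session", "animal_id", "arm", "bin_start_min", "bin_end_min", "flinches"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    drug_idx = sorted(
        int(m.group(1)) for c in df.columns if (m := _DRUG_COL.match(c))
    )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            flinches_raw = float(rowd["flinches"])
            if not flinches_raw.is_integer() or flinches_raw < 0:
                raise ValueError(
                    f"flinches must be a non-negative integer, got {rowd['flinches']!r}"
                )
            drug_doses = {}
            for k in drug_idx:
                drug = rowd.get(f"drug{k}")
                dose = rowd.get(f"dose{k}_mg_kg")
                if drug is None or (isinstance(drug, float) and math.isnan(drug)) or drug == "":
                    continue
                if dose is None or (isinstance(dose, float) and math.isnan(dose)) or dose == "":
                    raise ValueError(f"drug{k}={drug!r} given without dose{k}_mg_kg")
                drug_doses[str(drug)] = float(dose)
            records.append(
                FlinchRecord(
                    animal_id=str(rowd["animal_id"]),
                    arm=str(rowd["arm"]),
                    drug_doses=drug_doses,
                    bin_start=float(rowd["bin_start_min"]),
                    bin_end=float(rowd["bin_end_min"]),
                    flinches=int(flinches_raw),
                    session=str(rowd["session"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise _row_error(path, i, str(exc)) from None
    return FlinchDataset(records=records)


def write_flinch_csv(ds: FlinchDataset, path: Union[str, Path]) -> None:
    n_drugs = max((len(r.drug_doses) for r in ds.records), default=1) or 1
    rows = []
    for r in ds.records:
        row: dict[str, Any] = {
            "session": r.session,
            "animal_id": r.animal_id,
            "arm": r.arm,
        }
        for k, (drug, dose) in enumerate(sorted(r.drug_doses.items()), start=1):
            row[f"drug{k}"] = drug
            row[f"dose{k}_mg_kg"] = dose
        row.update(
            bin_start_min=r.bin_start, bin_end_min=r.bin_end, flinches=r.flinches
        )
        rows.append(row)
    cols = ["session", "animal_id", "arm"]
    for k in range(1, n_drugs + 1):
        cols += [f"drug{k}", f"dose{k}_mg_kg"]
    cols += ["bin_start_min", "bin_end_min", "flinches"]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)


def read_binding_csv(path: Union[str, Path]) -> list[BindingTimeCourse]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"session", "animal_id", "arm", "transporter", "time_min", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    courses = []
    keys = ["session", "animal_id", "arm", "transporter"]
    for (session, animal, arm, transporter), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("time_min")
        try:
            courses.append(
                BindingTimeCourse(
                    animal_id=str(animal),
                    arm=str(arm),
                    transporter=str(transporter),
                    points=tuple(
                        (float(t), float(s))
                        for t, s in zip(grp["time_min"], grp["signal"])
                    ),
                    session=str(session),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: animal {animal!r}: {exc}") from None
    return courses


def write_binding_csv(courses: Sequence[BindingTimeCourse], path: Union[str, Path]) -> None:
    rows = [
        {
            "session": tc.session,
            "animal_id": tc.animal_id,
            "arm": tc.arm,
            "transporter": tc.transporter,
            "time_min": t,
            "signal": s,
        }
        for tc in courses
        for t, s in tc.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_compound_csv(path: Union[str, Path]) -> list[CompoundProfile]:
    df = pd.read_csv(path)
    if "name" not in df.columns or not {"pic50_sert", "pic50_net"} <= set(df.columns):
        raise ValueError(f"{path}: need columns name, pic50_sert, pic50_net")
    out = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        def opt(key: str) -> Optional[float]:
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        try:
            out.append(
                CompoundProfile(
                    name=str(row["name"]),
                    pic50_sert=float(row["pic50_sert"]),
                    pic50_net=float(row["pic50_net"]),
                    pki_sert=opt("pki_sert"),
                    pki_net=opt("pki_net"),
                    fu_plasma=opt("fu_plasma"),
                    fu_brain=opt("fu_brain"),
                )
            )
        except (TypeError, ValueError) as exc:
            raise _row_error(path, i, str(exc)) from None
    return out


# ---------------------------------------------------------------------------
# Reports


def to_jsonable(obj: Any) -> Any:
    """Convert result objects to plain JSON-serialisable structures."""
    if isinstance(obj, DoseResponseFit):
        return {
            "drug_label": obj.drug_label,
            "ed50": obj.ed50,
            "log_ed50": obj.log_ed50,
            "hill": obj.hill,
            "ci95": list(obj.ci95) if obj.ci95 else None,
            "n_points": obj.n_points,
            "converged": obj.converged,
            "residual_sd": obj.residual_sd,
        }
    if isinstance(obj, IsobologramResult):
        return {
            "f": obj.design.f if obj.design else None,
            "ratio": obj.design.ratio if obj.design else None,
            "z_add": obj.z_add,
            "z_add_ci": list(obj.z_add_ci) if obj.z_add_ci else None,
            "z_obs": obj.z_obs,
            "z_obs_ci": list(obj.z_obs_ci) if obj.z_obs_ci else None,
            "interaction_index": obj.interaction_index,
            "verdict": obj.verdict,
        }
    if isinstance(obj, (GroupSummary, OccupancyRecord)):
        return dataclasses.asdict(obj)
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: to_jsonable(v) for k, v in obj.items()}
    return obj


def write_json_report(results: Any, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(to_jsonable(results), indent=2) + "\n")


def _fmt_ci(ci: Optional[Sequence[float]]) -> str:
    return f"({ci[0]:.3g}-{ci[1]:.3g})" if ci else "(CI absent)"


def format_fit(fit: DoseResponseFit) -> str:
    return (
        f"{fit.drug_label or 'fit'}: ED50 = {fit.ed50:.3g} mg/kg "
        f"{_fmt_ci(fit.ci95)}, Hill = {fit.hill:.2f}, n = {fit.n_points}"
        + ("" if fit.converged else "  [NOT CONVERGED]")
    )


def format_isobologram(res: IsobologramResult) -> str:
    lines = [
        f"additive ED50 (total dose): {res.z_add:.3g} mg/kg {_fmt_ci(res.z_add_ci)}",
        f"observed ED50 (total dose): {res.z_obs:.3g} mg/kg {_fmt_ci(res.z_obs_ci)}",
        f"interaction index: {res.interaction_index:.3g}",
        f"verdict: {res.verdict}",
    ]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Run manifests


@dataclass(frozen=True)
class RunManifest:
    """Record of one CLI run: command, config hash, inputs, outputs."""

    command: str
    config_hash: str
    input_paths: tuple[str, ...]
    output_paths: tuple[str, ...]
    timestamp: str
    seed: Optional[int] = None


def _config_hash(config: Any) -> str:
    blob = json.dumps(to_jsonable(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(
    path: Union[str, Path],
    command: str,
    config: Any,
    input_paths: Sequence[Union[str, Path]] = (),
    output_paths: Sequence[Union[str, Path]] = (),
    seed: Optional[int] = None,
) -> RunManifest:
    manifest = RunManifest(
        command=command,
        config_hash=_config_hash(config),
        input_paths=tuple(str(p) for p in input_paths),
        output_paths=tuple(str(p) for p in output_paths),
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        seed=seed,
    )
    Path(path).write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
    return manifest
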