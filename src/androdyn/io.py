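"""CSV/TSV/JSON readers and writers for the pipeline's record schemas."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from androdyn.chemotaxis import ChemotaxisPlate
from androdyn.demography import SexRatioTrajectory
from androdyn.errors import DataError
from androdyn.survival import SurvivalRecord

__all__ = ["read_survival_csv", "write_survival_csv", "read_plates_csv",
           "write_plates_csv", "write_trajectory_tsv", "write_json"]

SURVIVAL_COLUMNS = ["animal_id", "group", "day", "event"]
PLATE_COLUMNS = ["plate_id", "group", "n_super", "n_ctrl", "n_origin",
                 "n_total"]


def read_survival_csv(path: str | Path) -> list[SurvivalRecord]:
    """Read per-animal records (columns: animal_id, group, day, event)."""
    df = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"survival CSV missing columns {missing}")
    return [SurvivalRecord(animal_id=str(r.animal_id), group=str(r.group),
                           day=float(r.day), event=bool(r.event))
            for r in df.itertuples()]


def write_survival_csv(records: Iterable[SurvivalRecord],
                       path: str | Path) -> None:
    df = pd.DataFrame([{"animal_id": r.animal_id, "group": r.group,
                        "day": r.day, "event": int(r.event)}
                       for r in records])
    df.to_csv(path, index=False)


def read_plates_csv(path: str | Path) -> dict[str, list[ChemotaxisPlate]]:
    """Read chemotaxis plates grouped by their group label."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"plate CSV missing columns {missing}")
    groups: dict[str, list[ChemotaxisPlate]] = {}
    for r in df.itertuples():
        groups.setdefault(str(r.group), []).append(ChemotaxisPlate(
            n_super=int(r.n_super), n_ctrl=int(r.n_ctrl),
            n_origin=int(r.n_origin), n_total=int(r.n_total)))
    return groups


def write_plates_csv(groups: dict[str, Sequence[ChemotaxisPlate]],
                     path: str | Path) -> None:
    rows = []
    for group, plates in groups.items():
        for i, p in enumerate(plates):
            rows.append({"plate_id": f"{group}-{i:03d}", "group": group,
                         "n_super": p.n_super, "n_ctrl": p.n_ctrl,
                         "n_origin": p.n_origin, "n_total": p.n_total})
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def write_trajectory_tsv(trajectory: SexRatioTrajectory,
                         path: str | Path) -> None:
    """Trajectory as TSV (generation, male_fraction[, counts])."""
    data = {"generation": trajectory.generation,
            "male_fraction": trajectory.male_fraction}
    if trajectory.n_males is not None:
        data["n_males"] = trajectory.n_males
        data["n_hermaphrodites"] = trajectory.n_hermaphrodites
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
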