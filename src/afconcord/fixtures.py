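"""Packaged in-study reference tables.

The comparison analysis in this package was designed around a 12-patient
persistent-AF cohort in which reentrant-driver (RD) harboring atrial regions
were identified both by ECGI phase mapping and by simulations on
image-derived fibrotic substrates.  The per-patient agreement counts, the
region-by-stage RD occupancy for the six virtually ablated models, the
pooled 2x2 concordance table and the acute-outcome counts are shipped as
small CSV files so that every region-level statistic can be recomputed
without rerunning the clinical study.

Files are integrity-checked against packaged SHA-256 checksums on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

#: Anatomical region ids (see :func:`afconcord.substrate.partition_regions`).
REGION_NAMES = {
    1: "left PVs",
    2: "right PVs",
    3: "posterior LA",
    4: "superior RA",
    5: "inferior RA",
    6: "anterior LA",
    7: "inter-atrial groove",
}

#: Region ids belonging to each gross anatomical group.
LA_REGIONS = frozenset({1, 2, 3, 6})
RA_REGIONS = frozenset({4, 5})
IAG_REGIONS = frozenset({7})

_DATA_PKG = "afconcord.data"


class FixtureError(RuntimeError):
    """A packaged fixture is missing or fails its integrity check."""


def _read_fixture(name: str) -> bytes:
    root = resources.files(_DATA_PKG)
    path = root.joinpath(name)
    if not path.is_file():
        raise FixtureError(f"missing packaged fixture: {name}")
    return path.read_bytes()


def _verify(name: str, raw: bytes, checksums: dict[str, str]) -> None:
    digest = hashlib.sha256(raw).hexdigest()
    expected = checksums.get(name)
    if expected is None:
        raise FixtureError(f"no checksum recorded for fixture {name}")
    if digest != expected:
        raise FixtureError(
            f"checksum mismatch for fixture {name}: got {digest}, expected {expected}"
        )


@dataclass(frozen=True)
class StudyTables:
    """All packaged reference tables, parsed and integrity-checked.

    Attributes
    ----------
    table1 : per-patient counts of regions where the two modalities agreed
        (ECGI+/Sim+ or ECGI-/Sim-) and differed, 12 rows.
    table2 : region x stage RD occupancy for the 6 models that underwent the
        two-round virtual-ablation protocol; one row per (patient, stage)
        with stage in {ecgi, pre, post1, post2} and boolean region columns.
    concordance : pooled 2x2 region classification counts
        (ecgi_pos_sim_pos, ecgi_pos_sim_neg, ecgi_neg_sim_pos,
        ecgi_neg_sim_neg).
    outcome_counts : per-class acute ablation outcome counts
        (n_targets, positive_response, terminated).
    regional_counts : RD-harboring region counts per modality split into
        LA / RA / inter-atrial groove.
    classwise_regional : printed per-class per-region counts (the most
        frequent regions within a classification class).
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    concordance: pd.DataFrame
    outcome_counts: pd.DataFrame
    regional_counts: pd.DataFrame
    classwise_regional: pd.DataFrame


def load_study_tables() -> StudyTables:
    """Load and verify every packaged reference table.

    Raises
    ------
    FixtureError
        If a file is absent or its SHA-256 digest does not match the
        packaged manifest.
    """
    checksums = json.loads(_read_fixture("checksums.json").decode())

    def load(name: str) -> pd.DataFrame:
        raw = _read_fixture(name)
        _verify(name, raw, checksums)
        import io

        return pd.read_csv(io.BytesIO(raw))

    return StudyTables(
        table1=load("table1.csv"),
        table2=load("table2.csv"),
        concordance=load("concordance.csv"),
        outcome_counts=load("outcome_counts.csv"),
        regional_counts=load("regional_counts.csv"),
        classwise_regional=load("classwise_regional.csv"),
    )


def table2_stage_counts(fixtures: StudyTables, stage: str) -> list[int]:
    """Per-model RD-harboring region counts for one protocol stage.

    Stage is one of ``ecgi``, ``pre``, ``post1``, ``post2``; the returned
    list is ordered by patient id.
    """
    t2 = fixtures.table2
    sub = t2[t2["stage"] == stage].sort_values("patient_id")
    if sub.empty:
        raise ValueError(f"unknown stage: {stage!r}")
    return sub["n_regions"].astype(int).tolist()


def table2_region_sets(fixtures: StudyTables, stage: str) -> dict[int, set[int]]:
    """Occupied region-id sets per patient for one stage."""
    t2 = fixtures.table2
    sub = t2[t2["stage"] == stage]
    if sub.empty:
        raise ValueError(f"unknown stage: {stage!r}")
    cols = [c for c in t2.columns if c.startswith("r")]
    out: dict[int, set[int]] = {}
    for _, row in sub.iterrows():
        occupied = {i + 1 for i, c in enumerate(cols) if int(row[c]) == 1}
        out[int(row["patient_id"])] = occupied
    return out
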