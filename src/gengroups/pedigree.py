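"""Pedigree containers, I/O, validation, and genetic-group assignment.

A pedigree is an ordered list of individual/dam/sire records. Individuals
whose parents are unrecorded ("unknown") are linked to *phantom parents*:
notional, outbred, mutually unrelated members of the base population. When
unknown parents are genetically heterogeneous (e.g. local founders vs.
immigrants), the phantom parents are partitioned into *genetic groups*, each
with its own mean additive genetic value. This module handles the
bookkeeping: reading/writing pedigree tables, topological ordering,
missingness summaries, and assignment of every unknown-parent slot to a
genetic group (hard or fuzzy).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tokens interpreted as "parent unknown" when reading pedigree files.
DEFAULT_MISSING_CODES = frozenset({"NA", "0", "*", ""})

#: Sentinel for an unknown parent inside records (written out as "NA").
UNKNOWN = None


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, ...)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: its identifier, parents, and optional metadata.

    ``dam``/``sire`` are ``None`` when unknown.  ``sex`` is one of
    ``"F"``, ``"M"``, ``"U"``.
    """

    id: str
    dam: str | None = None
    sire: str | None = None
    cohort: int | None = None
    sex: str = "U"
    is_immigrant: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("empty individual id")
        if self.id == self.dam or self.id == self.sire:
            raise PedigreeError(f"individual {self.id!r} listed as its own parent")
        if self.sex not in ("F", "M", "U"):
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.id!r}")


class Pedigree:
    """An ordered collection of :class:`PedigreeRecord` with an id index.

    Construction does not require parents-before-offspring ordering; call
    :func:`validate_and_order` to obtain an ordered copy (a precondition of
    all relatedness recursions).
    """

    def __init__(self, records: Iterable[PedigreeRecord]):
        self.records: list[PedigreeRecord] = list(records)
        self.index: dict[str, int] = {}
        for pos, rec in enumerate(self.records):
            if rec.id in self.index:
                raise PedigreeError(f"duplicate id {rec.id}")
            self.index[rec.id] = pos
        for rec in self.records:
            for parent in (rec.dam, rec.sire):
                if parent is not None and parent not in self.index:
                    raise PedigreeError(
                        f"parent {parent!r} of {rec.id!r} not present as a record"
                    )
        both = set()
        for rec in self.records:
            if rec.dam is not None:
                both.add(("dam", rec.dam))
            if rec.sire is not None:
                both.add(("sire", rec.sire))
        used_as_dam = {p for role, p in both if role == "dam"}
        used_as_sire = {p for role, p in both if role == "sire"}
        for p in sorted(used_as_dam & used_as_sire):
            logger.warning("id %r appears as both dam and sire", p)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, Pedigree) and self.records == other.records

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def parent_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based positional codes of (dam, sire); -1 where unknown."""
        dam = np.array(
            [self.index[r.dam] if r.dam is not None else -1 for r in self.records],
            dtype=np.int64,
        )
        sire = np.array(
            [self.index[r.sire] if r.sire is not None else -1 for r in self.records],
            dtype=np.int64,
        )
        return dam, sire

    def is_ordered(self) -> bool:
        dam, sire = self.parent_codes()
        idx = np.arange(len(self))
        return bool(np.all(dam < idx) and np.all(sire < idx))

    def unknown_slots(self) -> list[tuple[str, str]]:
        """Every unknown-parent slot as ``(individual id, "dam"|"sire")``."""
        out: list[tuple[str, str]] = []
        for rec in self.records:
            if rec.dam is None:
                out.append((rec.id, "dam"))
            if rec.sire is None:
                out.append((rec.id, "sire"))
        return out


@dataclass
class MissingnessReport:
    """Counts and percentages of unknown parentage in a pedigree."""

    n_total: int
    n_unknown_dam: int
    n_unknown_sire: int
    pct_unknown_dam: float
    pct_unknown_sire: float
    n_founders: int
    n_nonfounder_unknown: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.n_total} individuals; unknown dams {self.n_unknown_dam} "
            f"({self.pct_unknown_dam:.1f}%), unknown sires {self.n_unknown_sire} "
            f"({self.pct_unknown_sire:.1f}%); founders {self.n_founders}; "
            f"non-founders with an unknown parent {self.n_nonfounder_unknown}"
        )


@dataclass
class GroupedPedigree:
    """A pedigree plus a genetic-group assignment for every unknown-parent slot.

    ``assignment`` maps each slot ``(id, "dam"|"sire")`` to a length-``r``
    membership vector over ``labels`` (a hard assignment is a unit vector).
    ``reference_group`` is the group whose mean effect is constrained to
    zero when fitting (group means are only estimable as contrasts).
    """

    base: Pedigree
    labels: Sequence[str]
    assignment: Mapping[tuple[str, str], np.ndarray]
    reference_group: str

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise PedigreeError("need at least one genetic group")
        if len(set(self.labels)) != len(self.labels):
            raise PedigreeError("duplicate group labels")
        if self.reference_group not in self.labels:
            raise PedigreeError(f"reference group {self.reference_group!r} not a label")
        r = len(self.labels)
        for slot in self.base.unknown_slots():
            if slot not in self.assignment:
                raise PedigreeError(
                    f"unknown-parent slot {slot} has no group assignment"
                )
            v = np.asarray(self.assignment[slot], dtype=float)
            if v.shape != (r,):
                raise PedigreeError(f"membership vector for {slot} has wrong length")
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-12:
                raise PedigreeError(
                    f"membership vector for {slot} must be non-negative and sum to 1"
                )

    @property
    def r(self) -> int:
        return len(self.labels)

    @property
    def reference_index(self) -> int:
        return list(self.labels).index(self.reference_group)

    def slot_vector(self, ind_id: str, which: str) -> np.ndarray:
        return np.asarray(self.assignment[(ind_id, which)], dtype=float)


def _hard(label: str, labels: Sequence[str]) -> np.ndarray:
    v = np.zeros(len(labels))
    v[list(labels).index(label)] = 1.0
    return v


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TRUE_TOKENS = {"1", "true", "t", "yes", "y", "immigrant"}


def read_pedigree(
    path: str | Path,
    missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> Pedigree:
    """Read a delimited pedigree table (header required) into a :class:`Pedigree`.

    The first three columns are taken as id/dam/sire unless ``column_map``
    names them; optional columns ``cohort``, ``sex``, ``immigrant`` are picked
    up by name.  Parents referenced but absent as rows are appended as founder
    records (with a warning).  Tokens in ``missing_codes`` mark unknown
    parents; a parent id simply absent from the file is also mapped to a
    founder record, so "absent" and "explicitly unknown" both end up
    resolvable (logged distinctly).
    """
    missing = set(missing_codes)
    if not missing:
        raise ValueError("missing_codes must be non-empty")
    path = Path(path)
    if sep is None:
        with open(path, newline="") as fh:
            sample = fh.read(4096)
        try:
            sep = csv.Sniffer().sniff(sample, delimiters=",;\t ").delimiter
        except csv.Error:
            sep = ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise PedigreeError(f"{path}: pedigree file needs at least 3 columns")

    cols = {c.lower().strip(): c for c in df.columns}
    cmap = dict(column_map or {})
    id_col = cmap.get("id", df.columns[0])
    dam_col = cmap.get("dam", df.columns[1])
    sire_col = cmap.get("sire", df.columns[2])
    cohort_col = cmap.get("cohort", cols.get("cohort"))
    sex_col = cmap.get("sex", cols.get("sex"))
    imm_col = cmap.get("immigrant", cols.get("immigrant") or cols.get("is_immigrant"))

    records: list[PedigreeRecord] = []
    seen: set[str] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            iid = str(row[id_col]).strip()
            if iid in missing:
                raise PedigreeError("id is a missing-value token")
            if iid in seen:
                raise PedigreeError(f"duplicate id {iid}")
            seen.add(iid)
            dam = str(row[dam_col]).strip()
            sire = str(row[sire_col]).strip()
            dam = None if dam in missing else dam
            sire = None if sire in missing else sire
            cohort = None
            if cohort_col and str(row.get(cohort_col, "")).strip() not in missing:
                cohort = int(float(str(row[cohort_col]).strip()))
            sex = "U"
            if sex_col:
                tok = str(row.get(sex_col, "")).strip().upper()
                if tok and tok not in missing:
                    sex = {"F": "F", "FEMALE": "F", "M": "M", "MALE": "M"}.get(tok, "U")
            imm = False
            if imm_col:
                imm = str(row.get(imm_col, "")).strip().lower() in _TRUE_TOKENS
            records.append(
                PedigreeRecord(iid, dam, sire, cohort=cohort, sex=sex, is_immigrant=imm)
            )
        except PedigreeError:
            raise
        except Exception as exc:
            raise PedigreeError(f"{path}:{lineno}: malformed row ({exc})") from exc

    known = {r.id for r in records}
    referenced = [
        p for r in records for p in (r.dam, r.sire) if p is not None and p not in known
    ]
    appended = []
    for p in dict.fromkeys(referenced):  # preserve first-reference order
        appended.append(PedigreeRecord(p))
        known.add(p)
    if appended:
        warnings.warn(
            f"{len(appended)} parent id(s) not present as rows were appended as "
            f"founders: {', '.join(r.id for r in appended[:5])}"
            + ("..." if len(appended) > 5 else ""),
            stacklevel=2,
        )
        logger.info(
            "parents absent from the records (appended as founders, distinct from "
            "explicitly-coded unknowns): %s",
            [r.id for r in appended],
        )
    return Pedigree(records + appended)


def write_pedigree(ped: Pedigree, path: str | Path, sep: str = ",") -> None:
    """Write a pedigree in the same dialect read_pedigree accepts (UNKNOWN -> "NA")."""
    rows = []
    for r in ped.records:
        rows.append(
            {
                "id": r.id,
                "dam": r.dam if r.dam is not None else "NA",
                "sire": r.sire if r.sire is not None else "NA",
                "cohort": r.cohort if r.cohort is not None else "NA",
                "sex": r.sex,
                "immigrant": int(r.is_immigrant),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Validation / ordering / summaries
# ---------------------------------------------------------------------------

def validate_and_order(ped: Pedigree) -> Pedigree:
    """Return a topologically ordered copy (parents before offspring).

    The order is stable: among individuals whose parents are all placed,
    input order breaks ties.  Idempotent on already-ordered pedigrees.
    Raises :class:`PedigreeError` listing one cycle if the pedigree is not
    acyclic.
    """
    n = len(ped)
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    npar = np.zeros(n, dtype=int)
    dam, sire = ped.parent_codes()
    for i in range(n):
        for p in (dam[i], sire[i]):
            if p >= 0:
                children[int(p)].append(i)
                npar[i] += 1

    import heapq

    ready = [i for i in range(n) if npar[i] == 0]
    heapq.heapify(ready)
    out: list[int] = []
    while ready:
        i = heapq.heappop(ready)
        out.append(i)
        for c in children[i]:
            npar[c] -= 1
            if npar[c] == 0:
                heapq.heappush(ready, c)
    if len(out) < n:
        stuck = next(i for i in range(n) if i not in set(out))
        cycle = [stuck]
        cur = stuck
        seen = {stuck}
        while True:
            cur = int(dam[cur]) if dam[cur] >= 0 and npar[int(dam[cur])] > 0 else int(sire[cur])
            cycle.append(cur)
            if cur in seen:
                break
            seen.add(cur)
        names = " -> ".join(ped.records[i].id for i in cycle)
        raise PedigreeError(f"pedigree contains a cycle: {names}")
    return Pedigree(ped.records[i] for i in out)


def missingness_summary(ped: Pedigree) -> MissingnessReport:
    """Counts/percentages of unknown dams and sires, founders, and non-founders."""
    n = len(ped)
    nd = sum(1 for r in ped.records if r.dam is None)
    ns = sum(1 for r in ped.records if r.sire is None)
    nf = sum(1 for r in ped.records if r.dam is None and r.sire is None)
    # non-founders with at least one unknown parent = unknown-any minus founders
    n_any = sum(1 for r in ped.records if r.dam is None or r.sire is None)
    nnf = n_any - nf
    return MissingnessReport(
        n_total=n,
        n_unknown_dam=nd,
        n_unknown_sire=ns,
        pct_unknown_dam=100.0 * nd / n if n else 0.0,
        pct_unknown_sire=100.0 * ns / n if n else 0.0,
        n_founders=nf,
        n_nonfounder_unknown=nnf,
    )


# ---------------------------------------------------------------------------
# Genetic-group assignment
# ---------------------------------------------------------------------------

def assign_groups(
    ped: Pedigree,
    rule: str = "single_group",
    *,
    labels: Sequence[str] | None = None,
    table: Mapping[str, str] | pd.DataFrame | None = None,
    reference: str | None = None,
) -> GroupedPedigree:
    """Assign every unknown-parent slot to a genetic group.

    Rules
    -----
    ``single_group``
        one group for all phantom parents (the basic-model base population).
    ``by_flag``
        two groups, ``founder``/``immigrant``: the unknown-parent slots of
        immigrant-flagged records go to ``immigrant``, all others to
        ``founder``; reference defaults to ``founder`` (true founders as the
        reference group).
    ``by_cohort``
        one group per cohort value observed among records with unknown
        parents (labels ``cohort<k>``); reference is the earliest cohort.
    ``table``
        explicit mapping id -> group label (applies to both of that
        individual's unknown slots), or a DataFrame with columns
        ``id``, ``slot`` (dam/sire/both) and ``group``.
    ``fuzzy``
        ``table`` is a DataFrame with columns ``id``, ``slot`` plus one
        probability column per group label; see
        :func:`gengroups.groups.fuzzy_memberships_from_table`.
    """
    slots = ped.unknown_slots()

    if rule == "single_group":
        labels = list(labels) if labels else ["g1"]
        if len(labels) != 1:
            raise PedigreeError("single_group rule takes exactly one label")
        assignment = {slot: _hard(labels[0], labels) for slot in slots}
        ref = reference or labels[0]
    elif rule == "by_flag":
        labels = list(labels) if labels else ["founder", "immigrant"]
        if len(labels) != 2:
            raise PedigreeError("by_flag rule takes exactly two labels")
        assignment = {}
        for iid, which in slots:
            rec = ped.records[ped.index[iid]]
            assignment[(iid, which)] = _hard(
                labels[1] if rec.is_immigrant else labels[0], labels
            )
        ref = reference or labels[0]
    elif rule == "by_cohort":
        cohorts = sorted(
            {
                ped.records[ped.index[iid]].cohort
                for iid, _ in slots
                if ped.records[ped.index[iid]].cohort is not None
            }
        )
        missing_cohort = [
            iid
            for iid, _ in slots
            if ped.records[ped.index[iid]].cohort is None
        ]
        if missing_cohort:
            raise PedigreeError(
                f"by_cohort rule: individual {missing_cohort[0]!r} with an "
                "unknown parent has no cohort"
            )
        labels = [f"cohort{c}" for c in cohorts]
        assignment = {
            (iid, which): _hard(
                f"cohort{ped.records[ped.index[iid]].cohort}", labels
            )
            for iid, which in slots
        }
        ref = reference or labels[0]
    elif rule == "table":
        if table is None:
            raise PedigreeError("table rule requires a table")
        mapping: dict[tuple[str, str], str] = {}
        if isinstance(table, pd.DataFrame):
            for row in table.itertuples(index=False):
                d = row._asdict()
                slot = str(d.get("slot", "both"))
                for which in ("dam", "sire") if slot == "both" else (slot,):
                    mapping[(str(d["id"]), which)] = str(d["group"])
        else:
            for iid, lab in table.items():
                mapping[(iid, "dam")] = lab
                mapping[(iid, "sire")] = lab
        labels = list(labels) if labels else sorted(set(mapping.values()))
        assignment = {}
        for slot in slots:
            if slot not in mapping:
                raise PedigreeError(
                    f"unknown-parent slot of individual {slot[0]!r} ({slot[1]}) "
                    "not covered by the grouping table"
                )
            assignment[slot] = _hard(mapping[slot], labels)
        ref = reference or labels[0]
    elif rule == "fuzzy":
        from .groups import fuzzy_memberships_from_table

        if table is None or not isinstance(table, pd.DataFrame):
            raise PedigreeError("fuzzy rule requires a membership DataFrame")
        labels = list(labels) if labels else [
            c for c in table.columns if c not in ("id", "slot")
        ]
        gp = GroupedPedigree(
            base=ped,
            labels=labels,
            assignment={s: np.full(len(labels), 1.0 / len(labels)) for s in slots},
            reference_group=reference or labels[0],
        )
        return fuzzy_memberships_from_table(gp, table)
    else:
        raise PedigreeError(f"unknown grouping rule {rule!r}")

    return GroupedPedigree(
        base=ped, labels=labels, assignment=assignment, reference_group=ref
    )
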