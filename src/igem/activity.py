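"""Harmonization of toxicology-database records into activity labels.

Three labelers convert GENE-TOX, IARC + CCRIS, and Tox21 record snapshots
into one ``active`` / ``inconclusive`` / ``inactive`` / ``missing`` label per
chemical and activity:

* genotoxicity — active if any GENE-TOX experiment is positive, inactive if
  all are negative, missing with no records;
* carcinogenicity — IARC groups 1/2A are active outright; groups 2B/3 are
  active with any positive CCRIS animal experiment and inconclusive
  otherwise; group 4 or absent IARC data is active with any positive and
  inactive with all-negative CCRIS data (missing with neither source);
* Tox21 — the parent compound's and its hydrochloride's outcomes are merged:
  {active, inconclusive} -> active, {active, inactive} -> inconclusive,
  {inactive, inconclusive} -> inactive, equal values stand, a single absent
  side defers to the other, both absent -> missing.

The {active, inactive} -> inconclusive rule reads oddly but is the
documented convention and is applied literally; ``merge_tox21`` accepts an
``active_inactive`` override for users who prefer a different resolution.
"""

from __future__ import annotations

import pandas as pd

LABELS = ("active", "inconclusive", "inactive", "missing")
GENETOX_OUTCOMES = ("positive", "negative")
CCRIS_OUTCOMES = ("positive", "negative")
IARC_GROUPS = ("1", "2A", "2B", "3", "4", "none")
TOX21_OUTCOMES = ("active", "inconclusive", "inactive", "none")


class VocabularyError(ValueError):
    """Raised when a record uses an outcome token outside its vocabulary."""


def _check(value: str, vocab: tuple[str, ...], what: str) -> str:
    if value not in vocab:
        raise VocabularyError(f"unknown {what} token {value!r}; expected one of {vocab}")
    return value


def label_genotoxicity(outcomes: list[str]) -> str:
    """Label genotoxicity from GENE-TOX experiment outcomes."""
    for o in outcomes:
        _check(o, GENETOX_OUTCOMES, "GENE-TOX outcome")
    if not outcomes:
        return "missing"
    return "active" if "positive" in outcomes else "inactive"


def label_carcinogenicity(group: str, ccris_outcomes: list[str]) -> str:
    """Label carcinogenicity from an IARC group and CCRIS animal outcomes.

    A chemical in group 2B/3 with no CCRIS records is "negative for all
    animal experiments" only vacuously; it is labelled inconclusive, and a
    group-4 chemical with no records is labelled missing, since neither
    source determines an outcome.
    """
    _check(group, IARC_GROUPS, "IARC group")
    for o in ccris_outcomes:
        _check(o, CCRIS_OUTCOMES, "CCRIS outcome")
    any_positive = "positive" in ccris_outcomes
    if group in ("1", "2A"):
        return "active"
    if group in ("2B", "3"):
        return "active" if any_positive else "inconclusive"
    # group 4 or no IARC data
    if any_positive:
        return "active"
    if ccris_outcomes:
        return "inactive"
    return "missing"


def merge_tox21(
    parent: str, hydrochloride: str, active_inactive: str = "inconclusive"
) -> str:
    """Merge the Tox21 outcomes of a compound and its hydrochloride.

    Symmetric in its two arguments.  ``active_inactive`` sets the resolution
    of the {active, inactive} conflict (default follows the documented
    convention of calling it inconclusive).
    """
    _check(parent, TOX21_OUTCOMES, "Tox21 outcome")
    _check(hydrochloride, TOX21_OUTCOMES, "Tox21 outcome")
    _check(active_inactive, LABELS[:3], "active/inactive resolution")
    if parent == "none" and hydrochloride == "none":
        return "missing"
    if parent == "none":
        return hydrochloride
    if hydrochloride == "none":
        return parent
    if parent == hydrochloride:
        return parent
    pair = {parent, hydrochloride}
    if pair == {"active", "inconclusive"}:
        return "active"
    if pair == {"active", "inactive"}:
        return active_inactive
    return "inactive"  # {inactive, inconclusive}


def build_activity_matrix(
    snapshot: dict[str, pd.DataFrame],
    activities: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the chemicals x activities label matrix from snapshot
    tables (keys ``genotox``, ``ccris``, ``iarc``, ``tox21``).

    Chemicals are joined across tables by their identifier column only.
    Rows that are missing in every column are dropped; the labeled-subset
    size is ``len(result)``.
    """
    genotox = snapshot.get("genotox", pd.DataFrame(columns=["chemical", "assay", "outcome"]))
    ccris = snapshot.get("ccris", pd.DataFrame(columns=["chemical", "experiment", "outcome"]))
    iarc = snapshot.get("iarc", pd.DataFrame(columns=["chemical", "group"]))
    tox21 = snapshot.get("tox21", pd.DataFrame(columns=["chemical", "activity", "form", "outcome"]))

    chemicals = sorted(
        set(genotox["chemical"]) | set(ccris["chemical"]) | set(iarc["chemical"]) | set(tox21["chemical"])
    )
    tox21_acts = sorted(tox21["activity"].unique()) if len(tox21) else []
    if activities is None:
        activities = ["genotoxicity", "carcinogenicity"] + tox21_acts

    geno_by_chem = {c: g["outcome"].tolist() for c, g in genotox.groupby("chemical")}
    ccris_by_chem = {c: g["outcome"].tolist() for c, g in ccris.groupby("chemical")}
    iarc_by_chem = {}
    for _, row in iarc.iterrows():
        iarc_by_chem[row["chemical"]] = _check(str(row["group"]), IARC_GROUPS, "IARC group")
    tox_by_chem: dict[tuple[str, str], dict[str, str]] = {}
    for _, row in tox21.iterrows():
        tox_by_chem.setdefault((row["chemical"], row["activity"]), {})[row["form"]] = row["outcome"]

    rows = {}
    for chem in chemicals:
        row = {}
        if "genotoxicity" in activities:
            row["genotoxicity"] = label_genotoxicity(geno_by_chem.get(chem, []))
        if "carcinogenicity" in activities:
            group = iarc_by_chem.get(chem, "none")
            row["carcinogenicity"] = label_carcinogenicity(group, ccris_by_chem.get(chem, []))
        for act in activities:
            if act in ("genotoxicity", "carcinogenicity"):
                continue
            forms = tox_by_chem.get((chem, act), {})
            row[act] = merge_tox21(forms.get("parent", "none"), forms.get("hydrochloride", "none"))
        rows[chem] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=activities)
    matrix.index.name = "chemical"
    if len(matrix):
        matrix = matrix[(matrix != "missing").any(axis=1)]
    return matrix


def matrix_from_csv(path: str) -> pd.DataFrame:
    """Read a serialized activity matrix; rebuilding from its own output is
    a fixed point of the serialization."""
    matrix = pd.read_csv(path, index_col="chemical")
    bad = set(matrix.to_numpy().ravel()) - set(LABELS)
    if bad:
        raise VocabularyError(f"unknown labels in matrix: {sorted(bad)}")
    return matrix
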