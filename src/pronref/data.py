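"""Record schema, loading, coding filters and descriptive summaries.

The unit of analysis is one coded story continuation: a participant saw a
two-referent context sentence (NP1 = first-mentioned, NP2 = second-mentioned)
followed by either a free prompt (blank line) or a pronoun prompt (personal
or demonstrative), and the annotators coded which referent the continuation
picked up and — for free prompts — with which referential form.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROMPTS = ("free", "personal", "demonstrative")
REFERENTS_RAW = ("NP1", "NP2", "both", "neither", "ambiguous", "other")
FORMS_RAW = ("personal", "demonstrative_dieser", "demonstrative_der", "other", "none")
EXCLUSION_CODES = (
    "none",
    "missing",
    "ungrammatical",
    "plural",
    "complex",
    "no_expression",
    "impersonal",
)

#: collapsed referential forms used for modelling: personal pronoun,
#: demonstrative pronoun (dieser- and der-type merged), anything else.
FORMS = ("PP", "DP", "other")

REQUIRED_COLUMNS = (
    "participant_id",
    "item_id",
    "prompt",
    "verb_class",
    "vtype",
    "referent_raw",
    "form_raw",
    "exclusion_code",
)

_FORM_COLLAPSE = {
    "personal": "PP",
    "demonstrative_dieser": "DP",
    "demonstrative_der": "DP",
    "other": "other",
    "none": "other",
}


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class ValidationError(ValueError):
    """A row carries a value outside the coding scheme."""


@dataclass
class LoadReport:
    n_rows: int
    counts: pd.DataFrame  # prompt x verb_class counts

    def __str__(self) -> str:  # pragma: no cover - display helper
        buf = io.StringIO()
        buf.write(f"{self.n_rows} records\n")
        buf.write(self.counts.to_string())
        return buf.getvalue()


@dataclass
class FilterReport:
    """Counts of records removed per reason by :func:`apply_coding_filters`."""

    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": k, "n_removed": v} for k, v in sorted(self.removed.items())]
        return pd.DataFrame(rows, columns=["reason", "n_removed"])


def _validate(df: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    checks = {
        "prompt": PROMPTS,
        "referent_raw": REFERENTS_RAW,
        "form_raw": FORMS_RAW,
        "exclusion_code": EXCLUSION_CODES,
    }
    for col, allowed in checks.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row}: invalid {col} value {df[col].iloc[row]!r}; "
                f"expected one of {allowed}"
            )
    vt = pd.to_numeric(df["vtype"], errors="coerce")
    if vt.isna().any() or not vt.isin([1, -1]).all():
        row = int(np.flatnonzero((~vt.isin([1, -1])).to_numpy())[0])
        raise ValidationError(f"row {row}: vtype must be +1 or -1")
    # exactly two verb-class labels map onto the +/-1 contrast
    mapping = df.groupby("verb_class")["vtype"].nunique()
    if (mapping > 1).any():
        raise ValidationError(
            f"verb_class {mapping[mapping > 1].index[0]!r} maps onto both vtype levels"
        )
    # a pronoun prompt fixes the form of the first referential expression
    pron = df["prompt"] != "free"
    expected = df.loc[pron, "prompt"].map(
        {"personal": "personal", "demonstrative": "demonstrative_dieser"}
    )
    mism = pron & ~(
        (df["form_raw"] == expected.reindex(df.index))
        | ((df["prompt"] == "demonstrative") & (df["form_raw"] == "demonstrative_der"))
    )
    if mism.any():
        row = int(np.flatnonzero(mism.to_numpy())[0])
        raise ValidationError(
            f"row {row}: pronoun-prompt form_raw {df['form_raw'].iloc[row]!r} "
            f"does not match prompt {df['prompt'].iloc[row]!r}"
        )
    dup = df.duplicated(subset=["participant_id", "item_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"row {row}: duplicate (participant_id, item_id) pair "
            f"({df['participant_id'].iloc[row]!r}, {df['item_id'].iloc[row]!r})"
        )


def load_continuations(
    path,
    schema_config: dict[str, str] | None = None,
    delimiter: str = ",",
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a delimited-text file of coded continuations.

    Parameters
    ----------
    path : str or file-like
        Location of a delimited text file with a header row.
    schema_config : dict, optional
        Mapping from the canonical column names (:data:`REQUIRED_COLUMNS`)
        to the names used in the file; identity by default.
    delimiter : str
        Field delimiter, comma by default.

    Returns
    -------
    (DataFrame, LoadReport)
        Validated records in file order and a per-condition count report.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8")
    if schema_config:
        rename = {v: k for k, v in schema_config.items()}
        df = df.rename(columns=rename)
    _validate(df)
    df = df.copy()
    df["vtype"] = pd.to_numeric(df["vtype"]).astype(int)
    counts = df.groupby(["prompt", "verb_class"]).size().unstack(fill_value=0)
    return df.reset_index(drop=True), LoadReport(n_rows=len(df), counts=counts)


def apply_coding_filters(df: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Reduce coded records to the analyzable subset.

    Drops records with a non-``none`` exclusion code or with a referent
    outside {NP1, NP2} (ambiguous, plural/both, neither, other), recodes the
    referent to the +/-1 contrast (NP1 = +1, NP2 = -1) and collapses the raw
    referential forms to {PP, DP, other}. Idempotent: the output passes
    through unchanged.
    """
    _validate(df)
    removed: dict[str, int] = {}
    excl = df["exclusion_code"] != "none"
    for code, n in df.loc[excl, "exclusion_code"].value_counts().items():
        removed[str(code)] = int(n)
    nonbinary = ~excl & ~df["referent_raw"].isin(["NP1", "NP2"])
    if nonbinary.any():
        removed["non-binary referent"] = int(nonbinary.sum())
    keep = ~excl & ~nonbinary
    out = df.loc[keep].copy()
    if out.empty:
        raise ValueError("no analyzable records after coding filters")
    out["ref"] = np.where(out["referent_raw"] == "NP1", 1, -1)
    out["form"] = out["form_raw"].map(_FORM_COLLAPSE)
    out["participant_index"] = pd.factorize(out["participant_id"])[0]
    out["item_index"] = pd.factorize(out["item_id"])[0]
    report = FilterReport(n_input=len(df), n_output=len(out), removed=removed)
    return out.reset_index(drop=True), report


@dataclass
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    degenerate: bool = False


def cohens_kappa(labels_a, labels_b) -> KappaResult:
    """Unweighted Cohen's kappa for two annotators.

    kappa = (p_o - p_e) / (1 - p_e) with p_e the marginal-product expected
    agreement. When both raters use a single category in perfect agreement,
    kappa is undefined (p_e = 1); the raw agreement is returned with
    ``degenerate=True`` and ``kappa=nan``.
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("label sequences must be non-empty")
    table = pd.crosstab(a, b)
    cats = table.index.union(table.columns)
    table = table.reindex(index=cats, columns=cats, fill_value=0)
    n = len(a)
    p_o = float(np.trace(table.to_numpy())) / n
    marg_a = table.sum(axis=1).to_numpy() / n
    marg_b = table.sum(axis=0).to_numpy() / n
    p_e = float(marg_a @ marg_b)
    if p_e >= 1.0 - 1e-12:
        return KappaResult(kappa=float("nan"), p_observed=p_o, p_expected=p_e,
                           degenerate=True)
    return KappaResult(kappa=(p_o - p_e) / (1.0 - p_e), p_observed=p_o,
                       p_expected=p_e)


def _normalized_binomial_ci(df: pd.DataFrame, value: str, cell_cols: list[str],
                            level: float = 0.95) -> pd.DataFrame:
    """Within-participant normalized 95% intervals (descriptive only).

    Two-step recipe: each participant's cell proportions are shifted so that
    the participant mean matches the grand mean (removing between-participant
    variability), then a normal-approximation binomial-style interval is
    computed on the normalized cell means across participants.
    """
    from scipy import stats

    per = (
        df.groupby(["participant_id", *cell_cols])[value].mean().rename("p").reset_index()
    )
    grand = per["p"].mean()
    pmean = per.groupby("participant_id")["p"].transform("mean")
    per["p_norm"] = per["p"] - pmean + grand
    z = stats.norm.ppf(0.5 + level / 2)
    out = per.groupby(cell_cols)["p_norm"].agg(["mean", "sem", "count"]).reset_index()
    out["ci_low"] = out["mean"] - z * out["sem"]
    out["ci_high"] = out["mean"] + z * out["sem"]
    return out


def condition_proportions(df: pd.DataFrame, intervals: bool = False):
    """Descriptive condition summaries of a filtered dataset.

    Returns a dict with

    ``np1`` : per prompt x verb class, proportion of NP1 continuations
        (the raw next-mention / interpretation biases).
    ``form`` : per verb class x referent among free-prompt records, the
        probability of each referential form in {PP, DP, other}.
    ``np1_intervals`` : optional normalized within-participant 95% bands.

    Empty cells are reported as NaN with a warning rather than silently 0/0.
    """
    if "ref" not in df.columns or "form" not in df.columns:
        raise ValueError("condition_proportions expects a filtered dataset")
    np1 = (
        df.assign(np1=(df["ref"] == 1).astype(float))
        .groupby(["prompt", "verb_class"])["np1"]
        .agg(proportion="mean", n="size")
        .reset_index()
    )
    free = df[df["prompt"] == "free"]
    if free.empty:
        warnings.warn("no free-prompt records: form-probability table is empty")
        form = pd.DataFrame(columns=["verb_class", "ref", *FORMS])
    else:
        form = (
            free.groupby(["verb_class", "ref"])["form"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=list(FORMS), fill_value=0.0)
            .reset_index()
        )
    out = {"np1": np1, "form": form}
    if intervals:
        out["np1_intervals"] = _normalized_binomial_ci(
            df.assign(np1=(df["ref"] == 1).astype(float)),
            "np1",
            ["prompt", "verb_class"],
        )
    return out
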