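"""Respondent records, emotion vocabulary, table I/O and the rare-association filter.

The atomic input unit is one survey respondent: an opaque id, five free
associations given to a single cue (post-lemmatization), two emotion labels
per association drawn from a fixed 20-label inventory, and optional attitude
scale scores (POT on 1-5, GM on 1-6, SDO on 1-7).

All counting downstream is *respondent-level*: a respondent contributes at
most one occurrence to a lemma's frequency, and at most one co-mention to a
pair, no matter how many of their five slots hold the same lemma after
lemma-map merging.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "EMOTION_LABELS",
    "SCALE_RANGES",
    "N_ASSOCIATIONS",
    "LABELS_PER_ASSOCIATION",
    "ResponseRecord",
    "AssociationVocabulary",
    "ValidationError",
    "FormatError",
    "ConfigurationError",
    "normalize_lemma",
    "read_responses",
    "write_responses",
    "read_lemma_map",
    "apply_lemma_map",
    "build_vocabulary",
]

#: Canonical emotion-label inventory (10 positive/negative pairs drawn from
#: basic-emotion theory). The tuple order defines the label index e = 0..19
#: used by the affective-profile matrix.
EMOTION_LABELS: tuple[str, ...] = (
    "interest",
    "alarm",
    "empathy",
    "contempt",
    "surprise",
    "indifference",
    "hope",
    "fear",
    "gratitude",
    "anger",
    "joy",
    "sadness",
    "calmness",
    "relief",
    "pride",
    "shame",
    "generosity",
    "envy",
    "love/sympathy",
    "hate/antipathy",
)

#: Likert attitude scales and their admissible score ranges.
SCALE_RANGES: dict[str, tuple[float, float]] = {
    "pot": (1.0, 5.0),
    "gm": (1.0, 6.0),
    "sdo": (1.0, 7.0),
}

N_ASSOCIATIONS = 5
LABELS_PER_ASSOCIATION = 2

_LABEL_SET = frozenset(EMOTION_LABELS)


class ValidationError(ValueError):
    """A record violates the data model (unknown label, out-of-range score...)."""


class FormatError(ValueError):
    """An input table does not have the expected columns or shape."""


class ConfigurationError(ValueError):
    """A configuration artefact (e.g. lemma map) is internally inconsistent."""


def normalize_lemma(text: str) -> str:
    """Whitespace-trim, case-fold and NFC-normalize an association string."""
    return unicodedata.normalize("NFC", text.strip().casefold())


@dataclass(frozen=True)
class ResponseRecord:
    """One respondent's associations, emotion labels and attitude scores.

    ``associations`` has exactly five slots; empty slots are stored as ``""``
    and flag the record as incomplete (kept for network construction on the
    associations present, excluded nowhere by default but reported).
    ``emotion_labels[k]`` is the unordered pair of labels the respondent
    attached to ``associations[k]`` (empty tuple for an empty slot).
    """

    respondent_id: str
    associations: tuple[str, ...]
    emotion_labels: tuple[tuple[str, ...], ...]
    attitude_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.associations) != N_ASSOCIATIONS:
            raise ValidationError(
                f"respondent {self.respondent_id!r}: expected {N_ASSOCIATIONS} "
                f"association slots, got {len(self.associations)}"
            )
        if len(self.emotion_labels) != N_ASSOCIATIONS:
            raise ValidationError(
                f"respondent {self.respondent_id!r}: expected {N_ASSOCIATIONS} "
                f"emotion-label pairs, got {len(self.emotion_labels)}"
            )
        for slot, (assoc, labels) in enumerate(
            zip(self.associations, self.emotion_labels), start=1
        ):
            for lab in labels:
                if lab not in _LABEL_SET:
                    raise ValidationError(
                        f"respondent {self.respondent_id!r}, slot {slot}: "
                        f"unknown emotion label {lab!r}"
                    )
            if assoc and len(labels) not in (0, LABELS_PER_ASSOCIATION):
                raise ValidationError(
                    f"respondent {self.respondent_id!r}, slot {slot}: expected "
                    f"{LABELS_PER_ASSOCIATION} emotion labels, got {len(labels)}"
                )
        for scale, score in self.attitude_scores.items():
            if scale not in SCALE_RANGES:
                raise ValidationError(
                    f"respondent {self.respondent_id!r}: unknown scale {scale!r}"
                )
            lo, hi = SCALE_RANGES[scale]
            if not (lo <= score <= hi):
                raise ValidationError(
                    f"respondent {self.respondent_id!r}: {scale} score {score} "
                    f"outside [{lo}, {hi}]"
                )

    @property
    def is_complete(self) -> bool:
        """True when all five association slots are non-empty."""
        return all(a for a in self.associations)

    def distinct_associations(self) -> frozenset[str]:
        """The respondent's set of distinct non-empty lemmas (counting unit)."""
        return frozenset(a for a in self.associations if a)


@dataclass(frozen=True)
class AssociationVocabulary:
    """Respondent-level lemma frequencies with a minimum-occurrence filter.

    ``frequency[lemma]`` counts respondents mentioning the lemma at least
    once; ``retained`` is the analysis vocabulary (frequency >= threshold),
    ordered by descending frequency, lexicographic within ties.
    """

    frequency: Mapping[str, int]
    min_occurrence: int
    retained: tuple[str, ...]

    @property
    def n_distinct(self) -> int:
        return len(self.frequency)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_retained_tokens(self) -> int:
        """Total respondent-mention count over the retained vocabulary."""
        return sum(self.frequency[l] for l in self.retained)

    def to_frame(self) -> pd.DataFrame:
        """Vocabulary report: lemma, count, retained flag."""
        retained_set = set(self.retained)
        rows = sorted(
            self.frequency.items(), key=lambda kv: (-kv[1], kv[0])
        )
        return pd.DataFrame(
            {
                "lemma": [l for l, _ in rows],
                "count": [c for _, c in rows],
                "retained": [l in retained_set for l, _ in rows],
            }
        )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_ID_COL = "id"
_ASSOC_COLS = [f"assoc_{k}" for k in range(1, N_ASSOCIATIONS + 1)]
_EMO_COLS = [
    f"emo_{k}{s}" for k in range(1, N_ASSOCIATIONS + 1) for s in ("a", "b")
]
_SCORE_COLS = list(SCALE_RANGES)


def read_responses(path: str | Path, sep: str = ",") -> list[ResponseRecord]:
    """Read a respondent table (one row per respondent) into validated records.

    The table must have columns ``id``, ``assoc_1..assoc_5`` and
    ``emo_1a,emo_1b,...,emo_5a,emo_5b``; the score columns ``pot``, ``gm``,
    ``sdo`` are optional. UTF-8, header row, comma-separated by default.

    Raises :class:`FormatError` for missing columns and :class:`ValidationError`
    (with the offending row number) for invalid values.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in [_ID_COL, *_ASSOC_COLS, *_EMO_COLS] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    score_cols = [c for c in _SCORE_COLS if c in df.columns]

    records: list[ResponseRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        associations = tuple(normalize_lemma(row[c]) for c in _ASSOC_COLS)
        labels: list[tuple[str, ...]] = []
        for k in range(1, N_ASSOCIATIONS + 1):
            pair = tuple(
                v
                for v in (row[f"emo_{k}a"].strip(), row[f"emo_{k}b"].strip())
                if v
            )
            labels.append(pair)
        scores: dict[str, float] = {}
        for c in score_cols:
            raw = row[c].strip()
            if raw:
                try:
                    scores[c] = float(raw)
                except ValueError as exc:
                    raise ValidationError(
                        f"{path} row {row_no}: non-numeric {c} score {raw!r}"
                    ) from exc
        try:
            records.append(
                ResponseRecord(
                    respondent_id=row[_ID_COL],
                    associations=associations,
                    emotion_labels=tuple(labels),
                    attitude_scores=scores,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {row_no}: {exc}") from exc
    return records


def write_responses(
    records: Iterable[ResponseRecord], path: str | Path, sep: str = ","
) -> None:
    """Write records in the standard respondent-table layout (round-trips)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {_ID_COL: rec.respondent_id}
        for k, assoc in enumerate(rec.associations, start=1):
            row[f"assoc_{k}"] = assoc
        for k, pair in enumerate(rec.emotion_labels, start=1):
            padded = tuple(pair) + ("",) * (LABELS_PER_ASSOCIATION - len(pair))
            row[f"emo_{k}a"], row[f"emo_{k}b"] = padded[:2]
        for scale in _SCORE_COLS:
            if scale in rec.attitude_scores:
                row[scale] = rec.attitude_scores[scale]
        rows.append(row)
    cols = [_ID_COL, *_ASSOC_COLS, *_EMO_COLS]
    cols += [c for c in _SCORE_COLS if any(c in r for r in rows)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def read_lemma_map(path: str | Path, sep: str = ",") -> dict[str, str]:
    """Read a two-column raw_form -> lemma merge table."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if not {"raw_form", "lemma"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns raw_form, lemma")
    return {
        normalize_lemma(r): normalize_lemma(l)
        for r, l in zip(df["raw_form"], df["lemma"])
    }


def apply_lemma_map(
    records: Iterable[ResponseRecord], merge_map: Mapping[str, str]
) -> list[ResponseRecord]:
    """Replace every association by its mapped lemma where the map applies.

    The map must be idempotent: a value may not itself map onward to another
    form (cyclic or chained maps raise :class:`ConfigurationError`). Duplicate
    lemmas created within one respondent's slots are kept in place; all
    downstream counting is per-respondent and de-duplicates them.
    """
    merge_map = {
        normalize_lemma(k): normalize_lemma(v) for k, v in merge_map.items()
    }
    chained = [
        raw
        for raw, lemma in merge_map.items()
        if lemma in merge_map and merge_map[lemma] != lemma
    ]
    if chained:
        raise ConfigurationError(
            f"lemma map is not idempotent: {sorted(chained)} map to forms that "
            "map onward"
        )
    out = []
    for rec in records:
        mapped = tuple(
            merge_map.get(a, a) if a else a for a in rec.associations
        )
        out.append(
            ResponseRecord(
                respondent_id=rec.respondent_id,
                associations=mapped,
                emotion_labels=rec.emotion_labels,
                attitude_scores=rec.attitude_scores,
            )
        )
    return out


def build_vocabulary(
    records: Sequence[ResponseRecord], min_occurrence: int = 3
) -> AssociationVocabulary:
    """Count respondents per lemma and apply the minimum-occurrence filter.

    Associations mentioned by fewer than ``min_occurrence`` respondents are
    idiosyncratic periphery rather than shared representation; dropping them
    is what makes the co-occurrence statistics stable. The default of 3
    matches the method's standard setting.
    """
    if min_occurrence < 1:
        raise ValueError(f"min_occurrence must be >= 1, got {min_occurrence}")
    freq: dict[str, int] = {}
    for rec in records:
        for lemma in rec.distinct_associations():
            freq[lemma] = freq.get(lemma, 0) + 1
    retained = tuple(
        sorted(
            (l for l, c in freq.items() if c >= min_occurrence),
            key=lambda l: (-freq[l], l),
        )
    )
    return AssociationVocabulary(
        frequency=freq, min_occurrence=min_occurrence, retained=retained
    )
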