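"""Questionnaire instruments and integer encoding of raw answers.

An instrument is an ordered bank of items; each item is either *binary*
(yes/no, coded 0/1) or *ordinal* with ``n_levels`` graded options coded
``0 .. n_levels - 1``.  The default bank mirrors a combined depression +
personality battery: 21 four-statement ordinal items (BDI-like) followed
by 85 binary items (EPQ-like, subscales E/N/P/L), 106 items in total.

Encoded responses form the answer matrix ``A`` (respondents x items),
which downstream modules standardize into bipartite edge weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ItemSpec",
    "InstrumentBank",
    "AnswerMatrix",
    "EncodingError",
    "ValidationError",
    "LIKERT5_LABELS",
    "default_item_bank",
    "encode_response",
    "decode_response",
    "build_answer_matrix",
    "read_responses_csv",
    "write_responses_csv",
]


class EncodingError(ValueError):
    """Raised when a raw answer token cannot be mapped to an item code."""


class ValidationError(ValueError):
    """Raised when a response table violates the instrument contract."""


#: Canonical agreement-ordered five-level labels; code ascends from
#: "strongly agree" (0) to "strongly disagree" (4).
LIKERT5_LABELS: tuple[str, ...] = (
    "strongly agree",
    "agree",
    "neutral",
    "disagree",
    "strongly disagree",
)

_BINARY_LABELS: tuple[str, str] = ("no", "yes")


@dataclass(frozen=True)
class ItemSpec:
    """Specification of a single questionnaire item.

    Parameters
    ----------
    item_id
        Unique identifier within an :class:`InstrumentBank`.
    kind
        ``"binary"`` (yes/no) or ``"ordinal"`` (graded options).
    n_levels
        Number of answer levels; 2 for binary, >= 2 for ordinal.
    labels
        Optional answer tokens in code order (index = integer code).
        Binary items default to ``("no", "yes")``.
    subscale
        Optional subscale tag (e.g. E/N/P/L for EPQ-like items).
    """

    item_id: str
    kind: str
    n_levels: int
    labels: tuple[str, ...] | None = None
    subscale: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "ordinal"):
            raise ValueError(f"item {self.item_id!r}: unknown kind {self.kind!r}")
        if self.n_levels < 2:
            raise ValueError(f"item {self.item_id!r}: n_levels must be >= 2")
        if self.kind == "binary" and self.n_levels != 2:
            raise ValueError(f"item {self.item_id!r}: binary items have exactly 2 levels")
        if self.labels is None and self.kind == "binary":
            object.__setattr__(self, "labels", _BINARY_LABELS)
        if self.labels is not None:
            if len(self.labels) != self.n_levels:
                raise ValueError(
                    f"item {self.item_id!r}: {len(self.labels)} labels for "
                    f"{self.n_levels} levels"
                )
            object.__setattr__(
                self, "labels", tuple(str(t).strip().lower() for t in self.labels)
            )

    def to_dict(self) -> dict:
        d = {"item_id": self.item_id, "kind": self.kind, "n_levels": self.n_levels}
        if self.labels is not None:
            d["labels"] = list(self.labels)
        if self.subscale is not None:
            d["subscale"] = self.subscale
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ItemSpec":
        labels = d.get("labels")
        return cls(
            item_id=str(d["item_id"]),
            kind=str(d["kind"]),
            n_levels=int(d["n_levels"]),
            labels=tuple(labels) if labels else None,
            subscale=d.get("subscale"),
        )


@dataclass(frozen=True)
class InstrumentBank:
    """Ordered, immutable collection of items defining the question-node set.

    Item order is fixed and defines the column order of every
    :class:`AnswerMatrix` built against this bank.
    """

    items: tuple[ItemSpec, ...]
    name: str = "instrument"

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item_ids in bank {self.name!r}: {dupes}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def n_levels(self) -> np.ndarray:
        """Per-item level counts, in bank order."""
        return np.array([it.n_levels for it in self.items], dtype=int)

    def index_of(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"item {item_id!r} not in bank {self.name!r}") from None

    def to_json(self, path=None) -> str:
        """Serialize as a JSON array of item dicts (the schema interchange format)."""
        text = json.dumps(
            {"name": self.name, "items": [it.to_dict() for it in self.items]},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "InstrumentBank":
        """Load from a JSON string, path, or already-parsed mapping/array."""
        if isinstance(source, (dict, list)):
            data = source
        else:
            text = str(source)
            if "\n" not in text and not text.lstrip().startswith(("[", "{")):
                with open(text) as fh:
                    data = json.load(fh)
            else:
                data = json.loads(text)
        if isinstance(data, list):  # bare item array
            return cls(items=tuple(ItemSpec.from_dict(d) for d in data))
        return cls(
            items=tuple(ItemSpec.from_dict(d) for d in data["items"]),
            name=data.get("name", "instrument"),
        )


def default_item_bank() -> InstrumentBank:
    """The 106-item default bank: 21 four-level ordinal items then 85 binary items.

    The ordinal block models a depression inventory whose items each offer
    four graded statements (coded 0..3, ascending severity).  The binary
    block models a yes/no personality questionnaire; subscale tags are
    assigned in blocks of E (extraversion, 21), N (neuroticism, 24),
    P (psychoticism, 20), and L (lie, 20) items.
    """
    items: list[ItemSpec] = [
        ItemSpec(item_id=f"bdi_{i + 1:02d}", kind="ordinal", n_levels=4)
        for i in range(21)
    ]
    subscale_blocks = [("E", 21), ("N", 24), ("P", 20), ("L", 20)]
    j = 0
    for tag, count in subscale_blocks:
        for _ in range(count):
            j += 1
            items.append(
                ItemSpec(item_id=f"epq_{j:02d}", kind="binary", n_levels=2, subscale=tag)
            )
    assert len(items) == 106
    return InstrumentBank(items=tuple(items), name="bdi_epq_106")


def encode_response(item: ItemSpec, raw) -> int:
    """Map a raw answer (token or integer) to its integer code.

    Integers (or digit strings) already in ``[0, n_levels - 1]`` pass
    through; label tokens are matched case-insensitively against the
    item's labels ("no" -> 0, "yes" -> 1 for binary items).

    Raises
    ------
    EncodingError
        If the token is unrecognized or the integer is out of range,
        naming the item and the offending token.
    """
    if isinstance(raw, (bool, np.bool_)):
        raw = int(raw)
    if isinstance(raw, (int, np.integer)):
        code = int(raw)
        if 0 <= code < item.n_levels:
            return code
        raise EncodingError(
            f"item {item.item_id!r}: code {code} outside [0, {item.n_levels - 1}]"
        )
    if isinstance(raw, (float, np.floating)):
        if float(raw).is_integer():
            return encode_response(item, int(raw))
        raise EncodingError(f"item {item.item_id!r}: non-integer code {raw!r}")
    token = str(raw).strip().lower()
    if token.lstrip("+-").isdigit():
        return encode_response(item, int(token))
    if item.labels is not None and token in item.labels:
        return item.labels.index(token)
    raise EncodingError(f"item {item.item_id!r}: unrecognized answer token {raw!r}")


def decode_response(item: ItemSpec, code: int) -> str:
    """Inverse of :func:`encode_response`: code -> label token (or digit string)."""
    code = int(code)
    if not 0 <= code < item.n_levels:
        raise EncodingError(
            f"item {item.item_id!r}: code {code} outside [0, {item.n_levels - 1}]"
        )
    if item.labels is not None:
        return item.labels[code]
    return str(code)


@dataclass
class AnswerMatrix:
    """Respondents x items matrix of encoded answers (the answer matrix ``A``).

    ``codes[i, j]`` is the integer answer of respondent ``i`` to the
    ``j``-th item of ``bank``; every entry lies in
    ``[0, bank.items[j].n_levels - 1]``.
    """

    codes: np.ndarray
    respondent_ids: list[str] = field(default_factory=list)
    bank: InstrumentBank | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 2:
            raise ValidationError("codes must be a 2-D respondents x items matrix")
        self.respondent_ids = [str(r) for r in self.respondent_ids]
        if len(self.respondent_ids) != self.codes.shape[0]:
            raise ValidationError(
                f"{len(self.respondent_ids)} respondent_ids for "
                f"{self.codes.shape[0]} rows"
            )
        if len(set(self.respondent_ids)) != len(self.respondent_ids):
            raise ValidationError("duplicate respondent_id")
        if self.bank is not None:
            if self.codes.shape[1] != len(self.bank):
                raise ValidationError(
                    f"{self.codes.shape[1]} columns for a {len(self.bank)}-item bank"
                )
            upper = self.bank.n_levels[None, :] - 1
            if self.codes.size and ((self.codes < 0) | (self.codes > upper)).any():
                i, j = np.argwhere((self.codes < 0) | (self.codes > upper))[0]
                raise ValidationError(
                    f"respondent {self.respondent_ids[i]!r}, item "
                    f"{self.bank.items[j].item_id!r}: code {self.codes[i, j]} "
                    f"outside [0, {self.bank.items[j].n_levels - 1}]"
                )

    @property
    def n_respondents(self) -> int:
        return self.codes.shape[0]

    @property
    def n_items(self) -> int:
        return self.codes.shape[1]

    def subset(self, row_indices) -> "AnswerMatrix":
        """New AnswerMatrix restricted to the given respondent rows (order kept)."""
        idx = np.asarray(row_indices, dtype=int)
        return AnswerMatrix(
            codes=self.codes[idx],
            respondent_ids=[self.respondent_ids[i] for i in idx],
            bank=self.bank,
        )


def build_answer_matrix(bank: InstrumentBank, rows) -> AnswerMatrix:
    """Encode tabular responses into an :class:`AnswerMatrix`.

    Parameters
    ----------
    bank
        The instrument; its item order defines the column order.
    rows
        A :class:`pandas.DataFrame` with a ``respondent_id`` column (or a
        named index) and one column per ``item_id``, or an iterable of
        per-respondent mappings ``{"respondent_id": ..., item_id: answer}``.
        Every row must answer every item; missing answers are rejected,
        not imputed.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
        if "respondent_id" not in df.columns:
            df = df.reset_index(names="respondent_id")
    else:
        df = pd.DataFrame(list(rows))
        if "respondent_id" not in df.columns:
            raise ValidationError("each row must carry a 'respondent_id'")

    respondent_ids = [str(r) for r in df["respondent_id"].tolist()]
    dupes = pd.Series(respondent_ids)
    if dupes.duplicated().any():
        raise ValidationError(
            f"duplicate respondent_id: {sorted(dupes[dupes.duplicated()].unique())}"
        )

    missing_cols = [iid for iid in bank.item_ids if iid not in df.columns]
    if missing_cols:
        raise ValidationError(f"responses missing item columns: {missing_cols}")

    n, k = len(respondent_ids), len(bank)
    codes = np.zeros((n, k), dtype=int)
    for j, item in enumerate(bank.items):
        col = df[item.item_id].tolist()
        for i, raw in enumerate(col):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                raise ValidationError(
                    f"respondent {respondent_ids[i]!r} missing answer for "
                    f"item {item.item_id!r}"
                )
            codes[i, j] = encode_response(item, raw)
    return AnswerMatrix(codes=codes, respondent_ids=respondent_ids, bank=bank)


def write_responses_csv(m: AnswerMatrix, path) -> None:
    """Write integer codes as CSV: ``respondent_id`` column then one column per item."""
    cols = m.bank.item_ids if m.bank is not None else [f"item_{j}" for j in range(m.n_items)]
    df = pd.DataFrame(m.codes, columns=cols)
    df.insert(0, "respondent_id", m.respondent_ids)
    df.to_csv(path, index=False)


def read_responses_csv(path, bank: InstrumentBank) -> AnswerMatrix:
    """Read a responses CSV (integer codes or label tokens) against ``bank``."""
    df = pd.read_csv(path, dtype={"respondent_id": str})
    return build_answer_matrix(bank, df)
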