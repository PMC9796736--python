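"""Delimited-text input/output for response data and results.

CSV dialect: comma-separated, header row, UTF-8; items are integer 0/1
columns named ``item1..itemJ`` (or any columns matching an ``item`` prefix);
group and covariate columns are referenced by name.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import DataError, ResponseData

__all__ = ["read_responses_csv", "write_responses_csv"]


def read_responses_csv(
    path,
    item_prefix: str = "item",
    covariate_col: str | None = None,
    group_col: str | None = None,
) -> ResponseData:
    """Load a headered response CSV into a :class:`ResponseData`.

    Group labels may be arbitrary; they are mapped to 0-based indices in
    sorted label order (the first label becomes the reference group).
    """
    df = pd.read_csv(path)
    item_cols = [c for c in df.columns if c.startswith(item_prefix)]
    if len(item_cols) < 2:
        raise DataError(
            f"found {len(item_cols)} item column(s) with prefix {item_prefix!r}; "
            "need at least 2"
        )
    # keep item1..itemJ in numeric order when the suffixes are numeric
    try:
        item_cols = sorted(item_cols, key=lambda c: int(c[len(item_prefix):]))
    except ValueError:
        pass
    Y = df[item_cols].to_numpy()
    covariate = df[covariate_col].to_numpy() if covariate_col else None
    groups = None
    if group_col:
        labels = df[group_col].to_numpy()
        uniq = np.unique(labels)
        lut = {lab: i for i, lab in enumerate(uniq)}
        groups = np.array([lut[x] for x in labels], dtype=np.int64)
    return ResponseData(Y, groups=groups, covariate=covariate)


def write_responses_csv(data: ResponseData, path) -> None:
    """Write responses (plus covariate/group columns when present)."""
    J = data.n_items
    df = pd.DataFrame(data.responses, columns=[f"item{j + 1}" for j in range(J)])
    if data.covariate is not None:
        df["covariate"] = data.covariate
    if data.groups is not None:
        df["group"] = data.groups
    df.to_csv(path, index=False)
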