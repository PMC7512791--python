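"""Reading and writing datasets and structures.

Dataset CSV dialect: one row per subject, a ``subject_id`` column followed
by one column per attribute and slice named ``<attr>__<t>`` with 0-based,
contiguous slice indices; cells hold state labels (arbitrary strings).

Structures are exchanged as plain-text edge lists, one line per directed
edge such as ``X0[t] -> X2[t+1]`` (``[t-1]`` etc. for deeper Markov lags),
with a header comment recording n, m and the attribute names, or as DOT
digraphs for rendering.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AttributeSpec,
    SlicedVariable,
    TimeSeriesDataset,
    TransitionStructure,
)

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_structure",
    "read_structure",
]


class DataFormatError(ValueError):
    """A dataset or structure file violates the expected dialect."""


def write_dataset(data: TimeSeriesDataset, path: str) -> None:
    """Write a dataset in the ``subject_id,<attr>__<t>,...`` CSV dialect,
    columns grouped by attribute in slice order."""
    cols = {"subject_id": [f"s{i}" for i in range(data.N)]}
    for a, spec in enumerate(data.attrs):
        for t in range(data.T + 1):
            cols[f"{spec.name}__{t}"] = [
                spec.values[code] for code in data.values[:, t, a]
            ]
    pd.DataFrame(cols).to_csv(path, index=False)


def _parse_columns(columns: Sequence[str]) -> tuple[list[str], dict[str, dict[int, str]]]:
    attrs_in_order: list[str] = []
    slices: dict[str, dict[int, str]] = {}
    for col in columns:
        if col == "subject_id":
            continue
        m = re.fullmatch(r"(.+)__(\d+)", col)
        if m is None:
            raise DataFormatError(
                f"column {col!r} does not match the '<attr>__<t>' convention"
            )
        name, t = m.group(1), int(m.group(2))
        if name not in slices:
            attrs_in_order.append(name)
            slices[name] = {}
        if t in slices[name]:
            raise DataFormatError(f"duplicate column for attribute {name!r} slice {t}")
        slices[name][t] = col
    return attrs_in_order, slices


def read_dataset(
    path: str, attr_values: Optional[dict[str, Sequence[str]]] = None
) -> TimeSeriesDataset:
    """Read a dataset CSV.

    Attributes are ordered by first appearance in the header.  State labels
    map to codes by first-occurrence order (scanning subjects, then slices)
    unless ``attr_values`` pins an explicit label order per attribute.
    """
    df = pd.read_csv(path, dtype=str)
    names, slices = _parse_columns(df.columns)
    if not names:
        raise DataFormatError("no '<attr>__<t>' data columns found")
    t_max = max(max(d) for d in slices.values())
    for name in names:
        missing = sorted(set(range(t_max + 1)) - set(slices[name]))
        if missing:
            raise DataFormatError(
                f"attribute {name!r} is missing column(s) for slice(s) {missing}"
            )
    N = len(df)
    if N == 0:
        raise DataFormatError("dataset has no subject rows")
    values = np.zeros((N, t_max + 1, len(names)), dtype=np.int64)
    attrs: list[AttributeSpec] = []
    for a, name in enumerate(names):
        block = df[[slices[name][t] for t in range(t_max + 1)]]
        bad = block.isna()
        if bad.to_numpy().any():
            row = int(np.argwhere(bad.to_numpy())[0][0])
            col = block.columns[int(np.argwhere(bad.to_numpy())[0][1])]
            raise DataFormatError(f"empty cell at row {row}, column {col!r}")
        flat = block.to_numpy()
        if attr_values is not None and name in attr_values:
            labels = list(attr_values[name])
            code = {lab: i for i, lab in enumerate(labels)}
            unknown = set(flat.ravel()) - set(labels)
            if unknown:
                raise DataFormatError(
                    f"attribute {name!r} has labels {sorted(unknown)} outside the "
                    f"configured values {labels}"
                )
        else:
            labels = list(pd.unique(flat.ravel()))
            code = {lab: i for i, lab in enumerate(labels)}
        if len(labels) < 2:
            # a constant column still needs two states to be a variable
            labels = labels + [f"_{name}_pad"]
        attrs.append(AttributeSpec(name, tuple(labels)))
        values[:, :, a] = np.vectorize(code.__getitem__)(flat)
    return TimeSeriesDataset(values=values, attrs=attrs)


def _slice_label(s: int, m: int) -> str:
    if s == m:
        return "t+1"
    d = m - 1 - s
    return "t" if d == 0 else f"t-{d}"


def write_structure(
    structure: TransitionStructure,
    fmt: str = "edge_list",
    attr_names: Optional[Sequence[str]] = None,
) -> str:
    """Serialise a transition structure as an edge list or a DOT digraph.

    Edge lines read ``A[t] -> B[t+1]``; ordering is deterministic: source
    slice, then source index, then target index.
    """
    n, m = structure.n, structure.m
    names = (
        list(attr_names) if attr_names is not None else [f"X{i}" for i in range(n)]
    )
    if len(names) != n:
        raise ValueError("attr_names length must equal n")
    edges = []
    for i in range(n):
        for sv in structure.past_parents[i]:
            edges.append((sv.slice, sv.attr, i))
        for j in structure.intra_parents[i]:
            edges.append((m, j, i))
    edges.sort()
    if fmt == "edge_list":
        lines = [f"# transition network n={n} m={m} attrs={','.join(names)}"]
        for s, src, dst in edges:
            lines.append(
                f"{names[src]}[{_slice_label(s, m)}] -> {names[dst]}[t+1]"
            )
        return "\n".join(lines) + "\n"
    if fmt == "dot":
        lines = ["digraph transition {", "  rankdir=LR;"]
        for s in range(m + 1):
            members = "; ".join(f'"{names[a]}_{s}"' for a in range(n))
            lines.append(f"  {{ rank=same; {members}; }}")
        for s in range(m + 1):
            for a in range(n):
                lines.append(
                    f'  "{names[a]}_{s}" [label="{names[a]}[{_slice_label(s, m)}]"];'
                )
        for s, src, dst in edges:
            lines.append(f'  "{names[src]}_{s}" -> "{names[dst]}_{m}";')
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown structure format {fmt!r}")


_EDGE_RE = re.compile(
    r"\s*(?P<src>.+?)\[(?P<sslice>t(?:[+-]\d+)?)\]\s*->\s*(?P<dst>.+?)\[t\+1\]\s*"
)
_HEADER_RE = re.compile(r"#\s*transition network n=(\d+) m=(\d+) attrs=(.*)")


def read_structure(text: str) -> tuple[TransitionStructure, list[str]]:
    """Parse an edge-list structure back into a TransitionStructure plus the
    attribute names recorded in its header."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DataFormatError("empty structure file")
    hm = _HEADER_RE.fullmatch(lines[0].strip())
    if hm is None:
        raise DataFormatError("missing '# transition network ...' header line")
    n, m = int(hm.group(1)), int(hm.group(2))
    names = hm.group(3).split(",") if hm.group(3) else [f"X{i}" for i in range(n)]
    index = {name: i for i, name in enumerate(names)}
    past = [set() for _ in range(n)]
    intra = [set() for _ in range(n)]
    for ln in lines[1:]:
        if ln.lstrip().startswith("#"):
            continue
        em = _EDGE_RE.fullmatch(ln)
        if em is None:
            raise DataFormatError(f"unparseable edge line: {ln!r}")
        src, dst = index[em.group("src")], index[em.group("dst")]
        label = em.group("sslice")
        if label == "t+1":
            intra[dst].add(src)
        else:
            d = 0 if label == "t" else int(label.split("-")[1])
            past[dst].add(SlicedVariable(src, m - 1 - d))
    struct = TransitionStructure(
        n, m, tuple(frozenset(s) for s in past), tuple(frozenset(s) for s in intra)
    )
    return struct, names
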