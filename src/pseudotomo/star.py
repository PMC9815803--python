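"""STAR file reading and writing (RELION dialect).

A STAR document is an ordered collection of named data blocks.  Each block
is either a key--value list (held as a dict) or a loop table (held as a
pandas DataFrame with typed columns).  Block order, column order and
numeric values round-trip exactly (floats to >= 6 significant digits).

Dialect: ``data_<name>`` headers, ``loop_`` tables with leading-underscore
labels (``_rlnSomething #1``), whitespace-separated cells, ``#`` comments
ignored outside of quoted strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = ["StarDocument", "StarParseError", "read_star", "write_star"]

Block = Union[dict, pd.DataFrame]


class StarParseError(ValueError):
    """Raised on malformed STAR syntax, naming the offending line."""


@dataclass
class StarDocument:
    """Ordered named blocks; each a key-value dict or a loop DataFrame."""

    blocks: dict[str, Block] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Block:
        return self.blocks[name]

    def __setitem__(self, name: str, block: Block) -> None:
        self.blocks[name] = block

    def __contains__(self, name: str) -> bool:
        return name in self.blocks

    def block_names(self) -> list[str]:
        return list(self.blocks)


def _typed(token: str):
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError:
        return token


def _tokenize(line: str) -> list[str]:
    # strip trailing comments; RELION tables do not quote strings in practice
    if "#" in line:
        line = line.split("#", 1)[0]
    return line.split()


def read_star(path) -> StarDocument:
    """Parse a STAR file into a :class:`StarDocument`.

    Numeric cells are typed (int before float); unknown columns are kept.
    Raises :class:`StarParseError` with the line number on malformed loops
    and ``FileNotFoundError`` on a missing file.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    doc = StarDocument()
    i = 0
    current: str | None = None
    kv: dict | None = None

    def flush_kv():
        nonlocal kv
        if current is not None and kv is not None:
            doc.blocks[current] = kv
        kv = None

    n_lines = len(lines)
    while i < n_lines:
        raw = lines[i]
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            i += 1
            continue
        if stripped.startswith("data_"):
            flush_kv()
            current = stripped[len("data_"):]
            kv = {}
            i += 1
            continue
        if current is None:
            raise StarParseError(f"line {i + 1}: content before any data_ block: {raw!r}")
        if stripped == "loop_":
            # parse loop header
            i += 1
            columns: list[str] = []
            while i < n_lines:
                s = lines[i].strip()
                if s.startswith("_"):
                    toks = _tokenize(s)
                    if not toks or not toks[0].startswith("_"):
                        raise StarParseError(f"line {i + 1}: malformed loop label: {lines[i]!r}")
                    columns.append(toks[0][1:])
                    i += 1
                elif not s or s.startswith("#"):
                    i += 1
                    if columns:
                        break
                else:
                    break
            if not columns:
                raise StarParseError(f"line {i + 1}: loop_ without column labels")
            rows = []
            while i < n_lines:
                s = lines[i].strip()
                if not s or s.startswith("#"):
                    i += 1
                    break
                if s.startswith("data_") or s == "loop_" or s.startswith("_"):
                    break
                toks = _tokenize(s)
                if len(toks) != len(columns):
                    raise StarParseError(
                        f"line {i + 1}: expected {len(columns)} cells, got {len(toks)}"
                    )
                rows.append([_typed(t) for t in toks])
                i += 1
            df = pd.DataFrame(rows, columns=columns)
            flush_kv()
            doc.blocks[current] = df
            current = None
            continue
        if stripped.startswith("_"):
            toks = _tokenize(stripped)
            if len(toks) < 2:
                raise StarParseError(f"line {i + 1}: key without value: {raw!r}")
            if kv is None:
                kv = {}
            kv[toks[0][1:]] = _typed(" ".join(toks[1:]) if len(toks) > 2 else toks[1])
            i += 1
            continue
        raise StarParseError(f"line {i + 1}: unexpected content: {raw!r}")
    flush_kv()
    return doc


def _fmt(value) -> str:
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, (int,)) or (hasattr(value, "dtype") and "int" in str(value.dtype)):
        return str(int(value))
    if isinstance(value, float) or (hasattr(value, "dtype") and "float" in str(value.dtype)):
        return f"{float(value):.9g}"
    return str(value)


def write_star(doc: StarDocument, path) -> None:
    """Write ``doc``; the output re-reads with value equality (floats < 1e-6
    relative) and preserved block/column order."""
    out: list[str] = []
    for name, block in doc.blocks.items():
        out.append("")
        out.append(f"data_{name}")
        out.append("")
        if isinstance(block, pd.DataFrame):
            out.append("loop_")
            for k, col in enumerate(block.columns, start=1):
                out.append(f"_{col} #{k}")
            for _, row in block.iterrows():
                out.append(" ".join(_fmt(v) for v in row))
        else:
            for key, value in block.items():
                out.append(f"_{key} {_fmt(value)}")
        out.append("")
    Path(path).write_text("\n".join(out) + "\n")
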