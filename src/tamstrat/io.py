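"""Plain-text interchange: GMT gene sets and small TSV tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .diffexp import SignatureSet


def write_gmt(sets: list[SignatureSet], path: str | Path) -> None:
    """Write gene sets in GMT format: name, description, then gene ids."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.direction, *s.genes]) + "\n")


def read_gmt(path: str | Path) -> list[SignatureSet]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, *genes = fields
            direction = desc if desc in ("up_in_A", "up_in_B") else "none"
            out.append(SignatureSet(name, tuple(genes), direction))
    return out


def write_ztable(ztable: pd.Series, path: str | Path) -> None:
    df = ztable.rename("z").to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_ztable(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "z" not in df.columns:
        raise ValueError(f"z table {path} must have a 'z' column")
    df.index = df.index.astype(str)
    return df["z"].astype(float)


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in genes), encoding="utf-8")


def read_gene_list(path: str | Path) -> list[str]:
    return [g for g in Path(path).read_text(encoding="utf-8").splitlines() if g]
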