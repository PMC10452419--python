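"""Readers and writers for edge lists, score tables and result files."""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping

from .multiplex import LayerNetwork
from .search import Subnetwork

__all__ = ["read_layer", "read_scores", "write_results", "write_score_table", "read_results"]


def _looks_like_header(tokens: list[str]) -> bool:
    lowered = [t.lower() for t in tokens]
    header_words = {
        "gene", "gene1", "gene2", "gene_a", "gene_b", "source", "target",
        "protein1", "protein2", "pvalue", "p-value", "p_value", "lfdr",
        "score", "symbol", "node1", "node2",
    }
    return any(t in header_words for t in lowered)


def read_layer(path: str | Path, name: str | None = None, weight: float = 1.0) -> LayerNetwork:
    """Parse a two-column TSV edge list into a network layer.

    Lines starting with '#' are comments; an optional header row is
    detected by common column-name tokens; duplicate edges (either
    orientation) are stored once and self-loops are dropped with a warning.
    """
    path = Path(path)
    edges: set[frozenset[str]] = set()
    genes: set[str] = set()
    self_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) < 2:
                tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            a, b = tokens[0].strip(), tokens[1].strip()
            if lineno == 1 and _looks_like_header([a, b]):
                continue
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty gene identifier")
            if a == b:
                self_loops += 1
                continue
            edges.add(frozenset((a, b)))
            genes.update((a, b))
    if self_loops:
        warnings.warn(f"{path}: dropped {self_loops} self-loop(s)", stacklevel=2)
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return LayerNetwork(name=name or path.stem, edges=edges, genes=genes, weight=weight)


def read_scores(path: str | Path, kind: str = "pvalue") -> dict[str, float]:
    """Parse a gene TAB value score table (p-values or precomputed lfdrs)."""
    if kind not in ("pvalue", "lfdr"):
        raise ValueError(f"unknown score kind {kind!r}")
    path = Path(path)
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) < 2:
                tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            gene = tokens[0].strip()
            if lineno == 1 and _looks_like_header(tokens[:2]):
                continue
            try:
                value = float(tokens[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value {tokens[1]!r}") from exc
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{path}:{lineno}: {kind} {value} outside [0, 1]")
            if gene in out and out[gene] != value:
                raise ValueError(
                    f"{path}:{lineno}: duplicate gene {gene!r} with conflicting values"
                )
            out[gene] = value
    if not out:
        raise ValueError(f"{path}: no scores found")
    return out


def write_score_table(table, path: str | Path) -> None:
    """Write the per-gene score table (gene, pvalue, z, lfdr) as TSV."""
    table.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_results(
    subnetworks: Iterable[Subnetwork],
    json_path: str | Path,
    tsv_path: str | Path | None = None,
    lfdrs: Mapping[str, float] | None = None,
) -> None:
    """Emit results as a JSON array plus an optional flat TSV view.

    Subnetworks keep their detection (seed) order; genes are listed
    lexicographically, so output is deterministic.
    """
    subs = list(subnetworks)
    with open(json_path, "w") as fh:
        json.dump([s.to_dict() for s in subs], fh, indent=1)
        fh.write("\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("subnetwork_id\tseed\tgene\tlfdr\n")
            for k, s in enumerate(subs):
                for g in sorted(s.genes):
                    lf = "" if lfdrs is None else f"{lfdrs.get(g, 1.0):.6g}"
                    fh.write(f"{k}\t{s.seed}\t{g}\t{lf}\n")


def read_results(json_path: str | Path) -> list[Subnetwork]:
    """Read back a results JSON; round-trips gene sets exactly."""
    with open(json_path) as fh:
        data = json.load(fh)
    return [
        Subnetwork(
            seed=d["seed"],
            genes=frozenset(d["genes"]),
            conductance=d["conductance"],
            est_fdr=d["est_fdr"],
            status=d["status"],
        )
        for d in data
    ]
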