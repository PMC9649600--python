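"""Optional subprocess bridge to DESeq2 for exact reference DE runs.

The core pipeline never depends on R; this wrapper shells out to a frozen R
script when an R runtime with DESeq2 is available and returns a table in the
same schema as :mod:`scnoise.diffexp`.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import pandas as pd

from .io import CountMatrix

_R_SCRIPT = Path(__file__).with_name("deseq2_bridge.R")


class OptionalDependencyError(RuntimeError):
    """Raised when the optional R/DESeq2 runtime is unavailable."""


def run_deseq2(
    counts: CountMatrix,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    out_path: str | Path | None = None,
    log2fc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
) -> tuple[pd.DataFrame, str]:
    """Run DESeq2 (default parameters) on a two-group comparison.

    Returns the result table (gene, baseMean, log2FC, se, wald_p, padj,
    significant) and the DESeq2 version string.  Raises
    :class:`OptionalDependencyError` when Rscript is not on PATH.
    """
    if shutil.which("Rscript") is None:
        raise OptionalDependencyError(
            "Rscript not found; install R with the DESeq2 package to use the "
            "bridge, or use the in-core nb_wald_de engine"
        )
    sub = counts.endogenous() if counts.is_spikein.any() else counts
    labels = pd.Series(labels)
    cells = [c for c in sub.cell_ids if c in labels.index and labels[c] in (group_a, group_b)]
    sub = sub.subset_cells(cells)
    with tempfile.TemporaryDirectory(prefix="scnoise_deseq2_") as tmp:
        tmp = Path(tmp)
        counts_path = tmp / "counts.tsv"
        labels_path = tmp / "labels.tsv"
        result_path = Path(out_path) if out_path else tmp / "deseq2.tsv"
        sub.to_tsv(counts_path)
        pd.DataFrame({"cell_id": cells, "group": [labels[c] for c in cells]}).to_csv(
            labels_path, sep="\t", index=False
        )
        cmd = [
            "Rscript",
            "--vanilla",
            str(_R_SCRIPT),
            str(counts_path),
            str(labels_path),
            str(result_path),
            group_a,
            group_b,
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"DESeq2 bridge failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}"
            )
        version = ""
        for line in proc.stdout.splitlines():
            if line.startswith("DESEQ2_VERSION"):
                version = line.split("\t", 1)[1].strip()
        table = pd.read_csv(result_path, sep="\t")
    table["significant"] = (
        (table["log2FC"].abs() > log2fc_threshold) & (table["padj"] < padj_threshold)
    ).fillna(False)
    return table, version
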