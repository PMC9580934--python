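"""Shared I/O, run manifests and miniature test fixtures.

File conventions: bulk methylation ``X.tsv`` is written CpGs-in-rows,
samples-in-columns (the usual array-export orientation); proportions
``W.tsv`` samples-in-rows. Orientation is recorded in the header corner
label so a transposed file is caught on read. All writers/readers round-trip
values exactly (shortest-repr floats).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ParameterError
from .simulate import ScenarioConfig, SyntheticCohort, simulate_cohort

__all__ = [
    "read_matrix",
    "write_matrix",
    "save_cohort",
    "load_cohort",
    "write_manifest",
    "make_fixture",
    "FIXTURES",
]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def write_matrix(df: pd.DataFrame, path, corner: str = "id") -> None:
    """Write a labeled matrix as TSV/CSV (delimiter from the extension)."""
    df = df.copy()
    df.index.name = corner
    df.to_csv(path, sep=_sep_for(path))


def read_matrix(path, orientation: Optional[str] = None) -> pd.DataFrame:
    """Read a labeled numeric matrix, reporting defects with coordinates.

    Raises :class:`ParameterError` on duplicate row/column labels and on
    non-numeric cells (naming the row and column). ``orientation``, when
    given, must match the corner label written by :func:`write_matrix`
    (e.g. ``"cpg"`` for a CpGs-in-rows bulk matrix).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if orientation is not None and raw.index.name != orientation:
        raise ParameterError(
            f"{path.name}: expected rows labeled {orientation!r}, "
            f"found {raw.index.name!r} — transposed file?")
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ParameterError(f"{path.name}: duplicate row label {dup[0]!r}")
    dupc = raw.columns[raw.columns.duplicated()]
    if len(dupc):
        raise ParameterError(f"{path.name}: duplicate column label {dupc[0]!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParameterError(
            f"{path.name}: non-numeric cell at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r}: {raw.iat[i, j]!r}")
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParameterError(
            f"{path.name}: missing value at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r} (ragged row?)")
    return numeric


def write_manifest(outdir, config: dict, seed: int) -> None:
    """Record seed, package version and full config; makes runs replayable."""
    manifest = {"package": "dmdir", "version": __version__,
                "seed": int(seed), "config": config}
    Path(outdir, "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def save_cohort(cohort: SyntheticCohort, outdir, save_z: bool = False) -> Path:
    """Write a cohort as X.tsv / W.tsv / y.tsv / truth.tsv / config.json.

    The latent tensor is optionally saved as ``Z.npz`` (binary, off by
    default); everything else is plain text.
    """
    from .evaluate import truth_table  # local import: avoid cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = pd.DataFrame(cohort.X.T, index=cohort.cpg_ids, columns=cohort.sample_ids)
    write_matrix(X, outdir / "X.tsv", corner="cpg")
    W = pd.DataFrame(cohort.W, index=cohort.sample_ids, columns=cohort.celltype_ids)
    write_matrix(W, outdir / "W.tsv", corner="sample")
    y = pd.DataFrame({"y": cohort.y}, index=cohort.sample_ids)
    write_matrix(y, outdir / "y.tsv", corner="sample")
    truth = truth_table(cohort.truth, cohort.cpg_ids, cohort.celltype_ids)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    (outdir / "config.json").write_text(
        json.dumps(cohort.config.to_dict(), indent=2) + "\n")
    if save_z:
        np.savez_compressed(outdir / "Z.npz", Z=cohort.Z, noise=cohort.noise)
    write_manifest(outdir, cohort.config.to_dict(), cohort.config.seed)
    return outdir


def load_cohort(outdir) -> dict:
    """Load the TSV cohort layout back into arrays and labels."""
    outdir = Path(outdir)
    X = read_matrix(outdir / "X.tsv", orientation="cpg")
    W = read_matrix(outdir / "W.tsv", orientation="sample")
    y = read_matrix(outdir / "y.tsv", orientation="sample")
    truth = pd.read_csv(outdir / "truth.tsv", sep="\t")
    config = json.loads((outdir / "config.json").read_text())
    out = {
        "X": X.to_numpy().T, "W": W.to_numpy(),
        "y": y["y"].to_numpy().astype(int),
        "truth": truth, "config": ScenarioConfig.from_dict(config),
        "cpg_ids": list(X.index), "sample_ids": list(X.columns),
        "celltype_ids": list(W.columns),
    }
    zpath = outdir / "Z.npz"
    if zpath.exists():
        with np.load(zpath) as z:
            out["Z"] = z["Z"]
            out["noise"] = z["noise"]
    return out


def _fixture_config(**kw) -> ScenarioConfig:
    base = dict(n=60, m=30, m_true=3, k=3, dirichlet_alpha=(3.0, 2.0, 1.0),
                seed=11)
    base.update(kw)
    return ScenarioConfig(**base)


#: registered miniature cohorts for the test suite; each entry documents the
#: invariant it exercises.
FIXTURES = {
    # effect-free X|Y cohort: phenotype exchangeable, null calibration
    "null-xgy": lambda: _fixture_config(direction="xgy", scenario="uni1c",
                                        effect_size=0.0),
    # one strongly shifted cell type per CpG: power / localization checks
    "strong-uni1c": lambda: _fixture_config(direction="xgy", scenario="uni1c",
                                            effect_size=4.0),
    # methylation drives the phenotype with little liability noise:
    # liability recomputable from the stored tensor
    "strong-ygx": lambda: _fixture_config(direction="ygx", scenario="uni1c",
                                          effect_size=4.0, liability_sd=0.1),
    # opposite-sign effects within each CpG: sign-structure checks
    "bi2c": lambda: _fixture_config(direction="xgy", scenario="bi2c",
                                    effect_size=2.0),
    # zero variances: X equals W @ mu exactly (mixture identity, noiseless)
    "degenerate-noiseless": lambda: _fixture_config(
        direction="xgy", scenario="uni1c", effect_size=0.0,
        sigma_range=(0.0, 0.0), tau_range=(0.0, 0.0)),
}


def make_fixture(name: str, outdir=None, save_z: bool = False) -> SyntheticCohort:
    """Build a registered deterministic miniature cohort (n=60, m=30, k=3)."""
    if name not in FIXTURES:
        raise ParameterError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    cohort = simulate_cohort(FIXTURES[name]())
    if outdir is not None:
        save_cohort(cohort, outdir, save_z=save_z)
    return cohort
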