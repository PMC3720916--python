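"""Colony-count tables, configuration files, and the synthetic fixture generator.

A colony table is delimited text (comma or tab, auto-detected) with header
columns ``dose, n, count, frequency, provenance``: one row per (dose, size)
pair.  ``n = 50`` may stand for the pooled >= 50-cell (clonogenic) class in
generator output.  Frequencies are percentages; which denominator they refer
to (all colonies vs >= 2-cell colonies) is the producer's choice and is
preserved verbatim -- conversion happens at analysis boundaries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .branching import ColonySizeDistribution, P1Schedule, pmf_schedule
from .errors import DomainError, FormatError
from .lattice import LatticeConfig, run_batch

__all__ = [
    "ColonyTable",
    "read_colony_table",
    "write_colony_table",
    "generate_synthetic_counts",
    "read_config",
]

COLUMNS = ["dose", "n", "count", "frequency", "provenance"]
PROVENANCES = {"observed", "estimated", "simulated"}


@dataclass
class ColonyTable:
    """Tidy per-(dose, size) colony records backed by a pandas DataFrame."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        for col in ("dose", "n"):
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
        if "count" not in df.columns and "frequency" not in df.columns:
            raise FormatError("need at least one of 'count' or 'frequency'")
        for col in ("count", "frequency"):
            if col not in df.columns:
                df[col] = np.nan
        if "provenance" not in df.columns:
            df["provenance"] = "observed"
        df["dose"] = df["dose"].astype(str)
        df["n"] = df["n"].astype(int)
        bad = df.index[df["n"] < 1].tolist()
        if bad:
            raise FormatError(f"non-positive colony size in row(s) {bad}")
        bad = df.index[df["count"].fillna(0) < 0].tolist()
        if bad:
            raise FormatError(f"negative count in row(s) {bad}")
        bad = df.index[df["frequency"].fillna(0) < 0].tolist()
        if bad:
            raise FormatError(f"negative frequency in row(s) {bad}")
        unknown = set(df["provenance"].dropna()) - PROVENANCES
        if unknown:
            raise FormatError(f"unknown provenance value(s) {sorted(unknown)}")
        dup = df.duplicated(subset=["dose", "n"])
        if dup.any():
            pairs = df.loc[dup, ["dose", "n"]].itertuples(index=False)
            raise FormatError(
                "duplicate (dose, n) pair(s): " + ", ".join(map(str, pairs)))
        self.data = (df[COLUMNS].sort_values(["dose", "n"])
                     .reset_index(drop=True))

    def __len__(self):
        return len(self.data)

    @property
    def doses(self) -> list[str]:
        return sorted(self.data["dose"].unique())

    @property
    def frequency_only(self) -> pd.Series:
        """Rows carrying a frequency but no raw count."""
        return self.data["count"].isna() & self.data["frequency"].notna()

    def to_distribution(self, dose: str, denominator: str = "all",
                        n_max: int | None = None) -> ColonySizeDistribution:
        """Distribution of one dose, as percent of the chosen denominator.

        ``denominator="all"`` uses every colony of the dose (including any
        pooled clonogenic class); ``"ge2"`` restricts to >= 2-cell colonies.
        Frequencies are recomputed from counts when present, otherwise taken
        as stored.  ``n_max`` optionally drops larger size classes *after*
        the denominator is formed.
        """
        if denominator not in ("all", "ge2"):
            raise DomainError(f"unknown denominator {denominator!r}")
        sub = self.data[self.data["dose"] == str(dose)]
        if sub.empty:
            raise DomainError(f"no rows for dose {dose!r}")
        f1_estimated = bool(
            ((sub["n"] == 1) & (sub["provenance"] == "estimated")).any())
        if sub["count"].notna().all():
            denom_rows = sub if denominator == "all" else sub[sub["n"] >= 2]
            total = denom_rows["count"].sum()
            if total <= 0:
                raise DomainError("zero total count for dose")
            entries = {int(r.n): 100.0 * r.count / total
                       for r in sub.itertuples()}
            counts = {int(r.n): int(r.count) for r in sub.itertuples()}
            total = int(total)
        else:
            entries = {int(r.n): float(r.frequency) for r in sub.itertuples()
                       if np.isfinite(r.frequency)}
            counts, total = None, None
        if n_max is not None:
            entries = {n: f for n, f in entries.items() if n <= n_max}
            counts = None if counts is None else {
                n: k for n, k in counts.items() if n <= n_max}
        return ColonySizeDistribution(dose=str(dose), entries=entries,
                                      f1_estimated=f1_estimated,
                                      counts=counts, total=total)

    def sizes_expanded(self, dose: str) -> np.ndarray:
        """Colony sizes of one dose repeated by count (for binning)."""
        sub = self.data[(self.data["dose"] == str(dose))
                        & self.data["count"].notna()]
        return np.repeat(sub["n"].to_numpy(), sub["count"].astype(int).to_numpy())


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_colony_table(path, dialect: str | None = None) -> ColonyTable:
    """Read a delimited colony table; delimiter auto-detected (comma/tab)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = dialect if dialect is not None else _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty table: {path}") from None
    if df.empty:
        raise FormatError(f"empty table: {path}")
    # report malformed rows with 1-based file line numbers (header = line 1)
    try:
        df["n"] = pd.to_numeric(df["n"], errors="raise")
    except (KeyError, ValueError) as exc:
        bad = [i + 2 for i, v in enumerate(df.get("n", []))
               if pd.notna(v) and not str(v).strip().lstrip("-").isdigit()]
        raise FormatError(f"malformed 'n' on line(s) {bad or '?'}: {exc}") from None
    try:
        return ColonyTable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_colony_table(table: ColonyTable, path, sep: str = ",") -> None:
    """Write the canonical form; write -> read round-trips exactly."""
    df = table.data.copy()
    df["count"] = df["count"].astype("Int64")
    df.to_csv(path, sep=sep, index=False)


def generate_synthetic_counts(
    schedule: P1Schedule,
    n_colonies: int,
    seed: int | None,
    mode: str = "analytic",
    dose: str = "0",
    config: LatticeConfig | None = None,
) -> ColonyTable:
    """Draw a synthetic colony table emulating scored assay data.

    ``mode="analytic"`` draws a multinomial sample of ``n_colonies`` over
    sizes 1..49 from the branching pmf, with all remaining probability mass
    (clonogenic and still-growing colonies) pooled into the ``n = 50``
    class.  ``mode="lattice"`` instead scores colonies grown by the lattice
    simulator, with true sizes >= 50 likewise pooled.  Frequencies are
    percentages of all colonies (1-cell class included).
    """
    if n_colonies < 1:
        raise DomainError("n_colonies must be >= 1")
    if mode not in ("analytic", "lattice"):
        raise DomainError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "analytic":
        pmf = pmf_schedule(schedule, 49)
        probs = np.append(pmf, max(0.0, 1.0 - pmf.sum()))
        counts = rng.multinomial(n_colonies, probs / probs.sum())
    else:
        config = config or LatticeConfig()
        batch = run_batch(schedule, config, n_inocula=n_colonies, n_sets=1,
                          seed=int(rng.integers(2**31)))
        sizes = np.minimum(batch.final_sizes, 50)
        counts = np.bincount(sizes, minlength=51)[1:]
    ns = np.flatnonzero(counts) + 1
    rows = pd.DataFrame({
        "dose": str(dose),
        "n": ns,
        "count": counts[ns - 1],
        "frequency": 100.0 * counts[ns - 1] / n_colonies,
        "provenance": "simulated",
    })
    return ColonyTable(rows)


def read_config(path) -> dict:
    """Read a flat ``key = value`` configuration file into a dict.

    Values are parsed as int, then float, then bool, else kept as strings;
    blank lines and ``#`` comments are ignored.
    """
    out = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        for cast in (int, float):
            try:
                out[key] = cast(value)
                break
            except ValueError:
                continue
        else:
            out[key] = {"true": True, "false": False}.get(value.lower(), value)
    return out
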