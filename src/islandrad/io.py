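"""Readers, writers and run manifests for the pipeline's file formats.

Canonical formats: Newick for trees (branch lengths in myr), TSV for all
tables (UTF-8, '.' decimal separator, empty cell = missing), JSON for
configuration and run manifests.  All tables round-trip (write -> read ->
equal), which the test suite relies on for bit-exact diffs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .geoscape import Geography, TimeStrata, build_geography
from .trees import DatedTree


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_range_table(path) -> dict[str, set[str]]:
    """Taxon-by-region 0/1 TSV -> taxon -> set of region codes."""
    df = read_tsv(path, index_col=0)
    out = {}
    for taxon, row in df.iterrows():
        out[str(taxon)] = {c for c in df.columns if int(row[c]) == 1}
    return out


def ranges_to_indices(
    ranges: dict[str, set[str]], geography: Geography
) -> dict[str, frozenset[int]]:
    return {
        t: frozenset(geography.index(c) for c in codes)
        for t, codes in ranges.items()
    }


def write_range_table(
    ranges: dict[str, frozenset[int]], geography: Geography, path
) -> None:
    rows = {
        t: {c: int(geography.index(c) in r) for c in geography.regions}
        for t, r in sorted(ranges.items())
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "taxon"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# geography config
# ---------------------------------------------------------------------------

def read_geography_config(path, root_age: float | None = None):
    """Geography from JSON ({"regions": [{code, name, emergence_age_myr}]})
    or TSV (columns region_code, region_name, emergence_age_myr; blank age
    = always available)."""
    path = Path(path)
    if path.suffix == ".json":
        cfg = json.loads(path.read_text())
        entries = cfg["regions"]
        codes = [e["region_code"] for e in entries]
        ages = {
            e["region_code"]: float(e["emergence_age_myr"])
            for e in entries
            if e.get("emergence_age_myr") not in (None, "")
        }
        names = {
            e["region_code"]: e.get("region_name", e["region_code"])
            for e in entries
        }
    else:
        df = read_tsv(path)
        codes = [str(c) for c in df["region_code"]]
        ages = {
            str(r["region_code"]): float(r["emergence_age_myr"])
            for _, r in df.iterrows()
            if pd.notna(r.get("emergence_age_myr"))
        }
        names = {
            str(r["region_code"]): str(r.get("region_name", r["region_code"]))
            for _, r in df.iterrows()
        }
    return build_geography(codes, ages, root_age=root_age, names=names)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record attached to every emitted table."""

    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    software_version: str = ""

    def __post_init__(self):
        if not self.software_version:
            from . import __version__

            self.software_version = __version__

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _digest(path)

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.timings[name] = time.perf_counter() - self.t0
                return False

        return _Timer()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def read(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# stochastic-map export
# ---------------------------------------------------------------------------

def export_maps(mapset, geography: Geography, out_dir) -> None:
    """One TSV per map plus a JSON manifest of the run."""
    from .stochmap import map_to_dataframe

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(mapset.maps):
        write_tsv(map_to_dataframe(m, geography), out / f"map_{i:03d}.tsv")
    manifest = RunManifest(
        config={
            "model": mapset.spec.name,
            "max_range_size": mapset.spec.max_range_size,
            "d": mapset.params.d,
            "e": mapset.params.e,
            "j": mapset.params.j,
            "n_maps": mapset.n_maps,
        },
        seeds={"stochastic_maps": mapset.seed},
    )
    manifest.write(out / "manifest.json")
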