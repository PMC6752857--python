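"""End-to-end pipeline: descriptors → statistics → masked summary tables.

:class:`EnsembleComparison` is the top-level model object: built from the
two condition ensembles, a region set and a descriptor plan, its ``fit``
computes every configured descriptor in both conditions, the three
difference statistics with replica-level resampling quantiles, and returns
an :class:`EnsembleComparisonResult` that renders the masked and unmasked
summary tables, per-descriptor histogram data, and the H-bond network
difference export.

:func:`run_pipeline` drives the same flow from a YAML config (paths to
multi-model PDB replicas, chain→component map, regions, descriptor list,
seeds) and writes all artifacts as TSV/JSON.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import descriptors as desc
from .descriptors import DescriptorSeries, write_series_tsv
from .ensemble import (
    Component,
    RECEPTOR_COMPONENTS,
    RegionSet,
    TrajectoryEnsemble,
    load_ensemble,
    select_region,
)
from .errors import ConfigError, EnsdiffError
from .hbonds_network import (
    DEFAULT_DELTA_THRESHOLD,
    bond_difference_map,
    export_cylinders,
    filter_threshold,
)
from .stats import (
    DEFAULT_N_PERMUTATIONS,
    DEFAULT_TVD_BINS,
    ComparisonResult,
    DescriptorComparison,
    shared_bin_edges,
)

__all__ = [
    "DescriptorPlan",
    "EnsembleComparison",
    "EnsembleComparisonResult",
    "SummaryTable",
    "run_pipeline",
    "histogram_report",
    "default_descriptor_plan",
]

# Table column legend: d/r and tvd are dimensionless, d keeps descriptor
# units.  Short-hands used in the output header.
COLUMN_LEGEND = {
    "d_over_r": "mean difference / trimmed combined range (dimensionless)",
    "d": "difference of pooled means (descriptor units)",
    "tvd": "total variation distance between distributions (0..1)",
}


@dataclass(frozen=True)
class DescriptorPlan:
    """One row of the analysis: which descriptor on which region(s)."""

    name: str
    kind: str  # distance | rg | sasa | rmsf | hbonds
    regions: tuple[str, ...] = ()
    context: tuple[str, ...] | None = None  # sasa occlusion components
    fit_regions: tuple[str, ...] = ()  # rmsf superposition regions
    selection_components: tuple[str, str] = (
        Component.RECEPTOR_ALPHA.value,
        Component.RECEPTOR_BETA.value,
    )  # hbonds sides

    def __post_init__(self) -> None:
        if self.kind not in ("distance", "rg", "sasa", "rmsf", "hbonds"):
            raise ConfigError(f"unknown descriptor kind {self.kind!r}")
        need = {"distance": 2, "rg": 1, "sasa": 1, "rmsf": 1, "hbonds": 0}
        if len(self.regions) != need[self.kind]:
            raise ConfigError(
                f"{self.name}: kind {self.kind!r} needs {need[self.kind]} "
                f"region(s), got {len(self.regions)}"
            )
        if self.kind == "rmsf" and not self.fit_regions:
            raise ConfigError(f"{self.name}: rmsf needs fit_regions")


def _component_selection(ens: TrajectoryEnsemble, component: str):
    return np.nonzero(ens.topology.components == component)[0]


def _compute_descriptor(
    plan: DescriptorPlan, ens: TrajectoryEnsemble, regions: RegionSet
) -> DescriptorSeries:
    def reg(name: str):
        if name not in regions:
            raise ConfigError(f"{plan.name}: unknown region {name!r}")
        return regions[name]

    if plan.kind == "distance":
        s = desc.region_distance(ens, reg(plan.regions[0]),
                                 reg(plan.regions[1]))
    elif plan.kind == "rg":
        s = desc.radius_of_gyration(ens, reg(plan.regions[0]))
    elif plan.kind == "sasa":
        context = plan.context
        if context is not None:
            # drop context components absent from this condition's topology
            present = set(ens.topology.components)
            context = tuple(c for c in context if c in present)
            if not context:
                context = None
        s = desc.sasa(ens, reg(plan.regions[0]), context=context)
    elif plan.kind == "rmsf":
        s = desc.rmsf_series(
            ens,
            [reg(r) for r in plan.fit_regions],
            reg(plan.regions[0]),
        )
    elif plan.kind == "hbonds":
        sel_a = _component_selection(ens, plan.selection_components[0])
        sel_b = _component_selection(ens, plan.selection_components[1])
        s = desc.hbond_count(ens, sel_a, sel_b)
    else:  # pragma: no cover - guarded in __post_init__
        raise ConfigError(plan.kind)
    # normalise the name so both conditions compare as the same descriptor
    return DescriptorSeries(
        descriptor_name=plan.name,
        region_names=s.region_names,
        condition_label=s.condition_label,
        values=s.values,
        units=s.units,
    )


class SummaryTable:
    """Masked and unmasked descriptor × statistic matrices."""

    STAT_COLUMNS = ("d_over_r", "d", "tvd")

    def __init__(self, results: Mapping[str, ComparisonResult]):
        self.results = dict(results)

    def _frame(self, masked: bool) -> pd.DataFrame:
        rows = {}
        for name, r in self.results.items():
            if masked:
                rows[name] = {
                    "d_over_r": r.masked_dr,
                    "d": r.masked_d,
                    "tvd": r.masked_tvd,
                    "units_d": r.units,
                }
            else:
                rows[name] = {
                    "d_over_r": r.d_over_r,
                    "d": r.d,
                    "tvd": r.tvd,
                    "units_d": r.units,
                }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "descriptor"
        return df

    @property
    def masked(self) -> pd.DataFrame:
        return self._frame(masked=True)

    @property
    def unmasked(self) -> pd.DataFrame:
        return self._frame(masked=False)

    def write_tsv(self, path, masked: bool = True) -> None:
        df = self.masked if masked else self.unmasked
        with open(path, "w") as fh:
            for col, meaning in COLUMN_LEGEND.items():
                fh.write(f"# {col}: {meaning}\n")
            fh.write(
                "# masked: non-significant values (outside the top/bottom "
                "5% of the resampling null) set to zero\n"
                if masked
                else "# unmasked: raw statistic values\n"
            )
            df.to_csv(fh, sep="\t")


@dataclass
class EnsembleComparisonResult:
    """Fitted pipeline: per-descriptor comparison results + artifacts."""

    results: dict[str, ComparisonResult]
    series: dict[str, tuple[DescriptorSeries, DescriptorSeries]]
    parameters: dict = field(default_factory=dict)

    @property
    def summary_table(self) -> SummaryTable:
        return SummaryTable(self.results)

    def summary(self) -> str:
        lines = [
            "Ensemble comparison (bound − unbound); masked values are zero "
            "unless q ≥ 0.95 or q ≤ 0.05 (tvd: q ≥ 0.95 only)",
        ]
        df = self.summary_table.masked
        lines.append(df.to_string(float_format=lambda v: f"{v: .3f}"))
        notes = [
            f"  [{name}] {note}"
            for name, r in self.results.items()
            for note in r.notes
        ]
        if notes:
            lines.append("notes:")
            lines.extend(notes)
        return "\n".join(lines)

    def save_artifacts(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        st = self.summary_table
        paths["summary_masked"] = directory / "summary_masked.tsv"
        st.write_tsv(paths["summary_masked"], masked=True)
        paths["summary_unmasked"] = directory / "summary_unmasked.tsv"
        st.write_tsv(paths["summary_unmasked"], masked=False)
        paths["results_json"] = directory / "results.json"
        payload = {
            "parameters": self.parameters,
            "results": {k: r.to_dict() for k, r in self.results.items()},
        }
        with open(paths["results_json"], "w") as fh:
            json.dump(payload, fh, indent=2)
        hist_dir = directory / "histograms"
        hist_dir.mkdir(exist_ok=True)
        for name, (b, u) in self.series.items():
            safe = name.replace(" ", "_").replace("/", "-")
            histogram_report(
                b, u, self.parameters.get("bins", DEFAULT_TVD_BINS),
                hist_dir / f"{safe}.tsv",
            )
        paths["histograms"] = hist_dir
        tidy = directory / "descriptors.tsv"
        write_series_tsv(
            [s for pair in self.series.values() for s in pair], tidy
        )
        paths["descriptors"] = tidy
        return paths


class EnsembleComparison:
    """Model: two condition ensembles under a shared descriptor plan.

    Parameters
    ----------
    bound, unbound:
        The condition ensembles (bound may contain ligand components the
        unbound one lacks; receptor chains must match).
    regions:
        Named residue ranges used by the descriptor plan.
    plans:
        The descriptors to evaluate; defaults cover centroid distance,
        per-region RG/SASA (full and receptor-only context), per-region
        RMSF and the inter-chain H-bond count.
    """

    def __init__(
        self,
        bound: TrajectoryEnsemble,
        unbound: TrajectoryEnsemble,
        regions: RegionSet,
        plans: Sequence[DescriptorPlan] | None = None,
        bins: int = DEFAULT_TVD_BINS,
    ):
        if bound.condition_label != "bound" or (
            unbound.condition_label != "unbound"
        ):
            raise ConfigError(
                "ensembles must be labelled 'bound' and 'unbound'"
            )
        self.bound = bound
        self.unbound = unbound
        self.regions = regions
        self.plans = list(
            plans
            if plans is not None
            else default_descriptor_plan(regions, bound)
        )
        self.bins = bins

    def fit(
        self,
        n_perm: int = DEFAULT_N_PERMUTATIONS,
        seed: int | None = None,
        statistics: Sequence[str] = ("d", "dr", "tvd"),
    ) -> EnsembleComparisonResult:
        rng = np.random.default_rng(seed)
        results: dict[str, ComparisonResult] = {}
        series: dict[str, tuple[DescriptorSeries, DescriptorSeries]] = {}
        for plan in self.plans:
            try:
                s_bound = _compute_descriptor(plan, self.bound, self.regions)
                s_unbound = _compute_descriptor(
                    plan, self.unbound, self.regions
                )
                model = DescriptorComparison(s_bound, s_unbound,
                                             bins=self.bins)
                res = model.fit(
                    n_perm=n_perm, seed=rng, statistics=statistics
                )
            except EnsdiffError as exc:
                raise type(exc)(f"[{plan.name}] {exc}") from exc
            results[plan.name] = res
            series[plan.name] = (s_bound, s_unbound)
        return EnsembleComparisonResult(
            results=results,
            series=series,
            parameters={
                "n_perm": n_perm,
                "seed": seed,
                "bins": self.bins,
                "statistics": list(statistics),
                "descriptors": [p.name for p in self.plans],
            },
        )

    # -- H-bond network ------------------------------------------------------

    def hbond_difference(
        self,
        threshold: float = DEFAULT_DELTA_THRESHOLD,
        components: tuple[str, str] = (
            Component.RECEPTOR_ALPHA.value,
            Component.RECEPTOR_BETA.value,
        ),
    ):
        """Filtered inter-selection H-bond occupancy difference records."""
        recs = []
        sel_b = [
            _component_selection(self.bound, c) for c in components
        ]
        sel_u = [
            _component_selection(self.unbound, c) for c in components
        ]
        table_bound = desc.hbond_frequency_table(self.bound, *sel_b)
        table_unbound = desc.hbond_frequency_table(self.unbound, *sel_u)
        recs = bond_difference_map(table_bound, table_unbound)
        return filter_threshold(recs, threshold)


def default_descriptor_plan(
    regions: RegionSet, bound: TrajectoryEnsemble
) -> list[DescriptorPlan]:
    """One DIST row per loop pair plus RG/SASA/RMSF per region and the
    inter-chain H-bond count — the shape of the standard summary table."""
    receptor = tuple(c.value for c in RECEPTOR_COMPONENTS)
    names = list(regions)
    plans: list[DescriptorPlan] = []
    loops = [n for n in names if n.lower().startswith(("loop", "cdr"))]
    by_chain: dict[str, list[str]] = {}
    for n in loops:
        by_chain.setdefault(regions[n].chain_id, []).append(n)
    chains = sorted(by_chain)
    if len(chains) >= 2:
        for a in by_chain[chains[0]]:
            for b in by_chain[chains[1]]:
                plans.append(
                    DescriptorPlan(
                        name=f"DIST {a}-{b}", kind="distance",
                        regions=(a, b),
                    )
                )
    stems = [n for n in names if not n.lower().startswith(("loop", "cdr"))]
    fit = tuple(stems) if stems else tuple(names)
    has_ligand = any(
        not Component(c).is_receptor for c in set(bound.topology.components)
    )
    for n in names:
        plans.append(DescriptorPlan(name=f"RG {n}", kind="rg", regions=(n,)))
        plans.append(
            DescriptorPlan(name=f"SASA {n}", kind="sasa", regions=(n,))
        )
        if has_ligand:
            plans.append(
                DescriptorPlan(
                    name=f"SASA {n} noligand", kind="sasa", regions=(n,),
                    context=receptor,
                )
            )
        plans.append(
            DescriptorPlan(
                name=f"RMSF {n}", kind="rmsf", regions=(n,),
                fit_regions=fit,
            )
        )
    plans.append(DescriptorPlan(name="n of H-bonds", kind="hbonds"))
    return plans


def histogram_report(
    bound: DescriptorSeries,
    unbound: DescriptorSeries,
    bins: int,
    path: str | Path,
) -> Path:
    """Shared-bin occurrence counts per condition as TSV.

    Uses the same bin construction as the tvd statistic, so counts and tvd
    are consistent when given the same bin count.
    """
    path = Path(path)
    pooled = np.concatenate([bound.pooled(), unbound.pooled()])
    edges = shared_bin_edges(pooled, bins)
    cb, _ = np.histogram(bound.pooled(), bins=edges)
    cu, _ = np.histogram(unbound.pooled(), bins=edges)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["bin_left", "bin_right", "count_bound", "count_unbound"])
        for i in range(len(cb)):
            w.writerow(
                [f"{edges[i]:.6g}", f"{edges[i + 1]:.6g}",
                 int(cb[i]), int(cu[i])]
            )
    return path


def run_pipeline(
    config: Mapping | str | Path,
    output_dir: str | Path,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
) -> EnsembleComparisonResult:
    """Full run from a YAML config (or an equivalent dict).

    Config keys: ``bound``/``unbound`` (lists of multi-model PDB paths),
    ``chain_components`` (chain → component), ``regions`` (name → {chain,
    start, end}), optional ``descriptors`` (list of plan dicts), optional
    ``stats`` ({n_perm, bins, seed}).  Writes summary tables, histogram
    TSVs, the H-bond cylinder export and a JSON result bundle.
    """
    import yaml

    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    stats_cfg = dict(config.get("stats", {}))
    n_perm = int(stats_cfg.get("n_perm", n_perm))
    bins = int(stats_cfg.get("bins", DEFAULT_TVD_BINS))
    if seed is None:
        seed = stats_cfg.get("seed")

    chain_components = config["chain_components"]
    bound = load_ensemble(config["bound"], "bound", chain_components)
    unbound = load_ensemble(config["unbound"], "unbound", chain_components)
    regions = RegionSet.from_mapping(config["regions"])

    plans = None
    if "descriptors" in config:
        plans = [
            DescriptorPlan(
                name=p["name"],
                kind=p["kind"],
                regions=tuple(p.get("regions", ())),
                context=(
                    tuple(p["context"]) if p.get("context") else None
                ),
                fit_regions=tuple(p.get("fit_regions", ())),
            )
            for p in config["descriptors"]
        ]
    model = EnsembleComparison(bound, unbound, regions, plans=plans,
                               bins=bins)
    result = model.fit(n_perm=n_perm, seed=seed)
    output_dir = Path(output_dir)
    paths = result.save_artifacts(output_dir)

    threshold = float(
        config.get("hbond_delta_threshold", DEFAULT_DELTA_THRESHOLD)
    )
    records = model.hbond_difference(threshold=threshold)
    export_cylinders(
        records,
        bound,
        output_dir / "hbond_cylinders.tsv",
        viewer_script=output_dir / "hbond_cylinders.pml",
    )

    log = {
        "seed": seed,
        "n_perm": n_perm,
        "bins": bins,
        "hbond_delta_threshold": threshold,
        "bound_files": [str(p) for p in config["bound"]],
        "unbound_files": [str(p) for p in config["unbound"]],
        "artifacts": {k: str(v) for k, v in paths.items()},
    }
    with open(output_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return result
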