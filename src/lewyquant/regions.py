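"""Canonical brain-region registry and region-cluster mapping.

28 gray-matter regions are annotated per case: cortical gyri/sulci,
subcortical nuclei, the hippocampal subfields, amygdala and entorhinal
cortex, substantia nigra and locus coeruleus, and the olfactory bulb.
For the regression analyses regions are condensed into five clusters
(cortical, subcortical, hippocampal, amygdala-entorhinal, brainstem); the
olfactory bulb stays unassigned and is reported separately.  Substantia
nigra and locus coeruleus are annotated twice per slide (two squares whose
mean is used as a more robust regional value), recorded here as
``n_annotations``.

The registry ships as a versioned CSV resource and every mapping is
overridable at load time.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "CLUSTERS",
    "RegionRegistry",
    "load_registry",
]

CLUSTERS = (
    "cortical",
    "subcortical",
    "hippocampal",
    "amygdala_entorhinal",
    "brainstem",
    "unassigned",
)

#: Regions whose mean defines the "cortical summary" used in subgroup
#: assignment: the most α-syn-affected cortical areas.
CORTICAL_SUMMARY_REGIONS = (
    "cingulate_gyrus",
    "superior_temporal_gyrus",
    "middle_temporal_gyrus",
    "insular_gyrus",
)

#: Regions whose mean (or single available value) defines the brainstem summary.
BRAINSTEM_SUMMARY_REGIONS = ("substantia_nigra", "locus_coeruleus")


class RegionRegistry:
    """Region -> cluster mapping plus per-region annotation policy."""

    def __init__(self, table: pd.DataFrame):
        required = {"region", "cluster", "n_annotations"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"registry table lacks columns: {sorted(missing)}")
        if table["region"].duplicated().any():
            dupes = table.loc[table["region"].duplicated(), "region"].tolist()
            raise ValueError(f"duplicate regions in registry: {dupes}")
        bad = set(table["cluster"]) - set(CLUSTERS)
        if bad:
            raise ValueError(f"unknown clusters in registry: {sorted(bad)}")
        self.table = table.reset_index(drop=True)
        self._cluster = dict(zip(table["region"], table["cluster"]))
        self._n_annot = dict(zip(table["region"], table["n_annotations"].astype(int)))

    @property
    def regions(self) -> list[str]:
        return list(self.table["region"])

    def cluster_of(self, region: str) -> str:
        try:
            return self._cluster[region]
        except KeyError:
            raise KeyError(f"unknown region {region!r}") from None

    def n_annotations(self, region: str) -> int:
        return self._n_annot[region]

    def regions_in(self, cluster: str) -> list[str]:
        return [r for r, c in self._cluster.items() if c == cluster]

    def __contains__(self, region: str) -> bool:
        return region in self._cluster

    def __len__(self) -> int:
        return len(self._cluster)


def load_registry(path: str | None = None, cluster_overrides: dict[str, str] | None = None) -> RegionRegistry:
    """Load the region registry from a CSV (default: the shipped resource).

    ``cluster_overrides`` maps region name -> cluster and is applied on top,
    so alternative cluster definitions (e.g. moving the parahippocampal
    gyrus) need no edited resource file.
    """
    if path is None:
        ref = resources.files("lewyquant") / "_resources" / "region_registry.csv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    if cluster_overrides:
        unknown = set(cluster_overrides) - set(table["region"])
        if unknown:
            raise ValueError(f"cluster overrides for unknown regions: {sorted(unknown)}")
        table = table.copy()
        for region, cluster in cluster_overrides.items():
            table.loc[table["region"] == region, "cluster"] = cluster
    return RegionRegistry(table)
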