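"""Fixed two-layer host taxonomy, label screening, and per-order prediction modes.

The host label space is a small fixed tree.  Layer 1 holds five branches at
kingdom/phylum rank (Chordata, Invertebrate, Viridiplantae, Fungi, Bacteria);
layer 2 refines the Chordata branch into ten class/order-rank leaves (Primates
... Fish).  Reference labels are screened before training: orders with more
than ``min_order_size`` viruses drop host labels carried by fewer than
``min_label_count`` members, and orders whose mammalian layer-2 records are
scarce collapse all mammalian classes into a single merged ``Mammalia`` node.

Each virus order is then assigned one of three prediction modes:

``direct_assign``
    every reference in the order carries the same leaf host label, so queries
    receive that label without a trained model;
``layer1_only``
    multiple layer-1 hosts but no layer-2 annotations;
``two_layer``
    layer-2 annotations exist, so a second classification layer refines
    Chordata predictions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LAYER1_LABELS",
    "LAYER2_LABELS",
    "MAMMAL_LAYER2_LABELS",
    "MERGED_MAMMAL_LABEL",
    "ORDER_REGISTRY",
    "HostTaxonomy",
    "VirusRecord",
    "OrderMode",
    "ScreeningReport",
    "build_default_taxonomy",
    "screen_labels",
    "order_mode",
    "host_homogeneity",
    "load_host_distribution",
    "expand_distribution_to_records",
]

LAYER1_LABELS = ("Chordata", "Invertebrate", "Viridiplantae", "Fungi", "Bacteria")
LAYER2_LABELS = (
    "Primates",
    "Rodentia",
    "Carnivora",
    "Artiodactyla",
    "Chiroptera",
    "Other Mammalia",
    "Aves",
    "Reptilia",
    "Amphibia",
    "Fish",
)
#: layer-2 leaves collapsed into the merged node when mammalian data are scarce
MAMMAL_LAYER2_LABELS = (
    "Primates",
    "Rodentia",
    "Carnivora",
    "Artiodactyla",
    "Chiroptera",
    "Other Mammalia",
)
MERGED_MAMMAL_LABEL = "Mammalia"

#: the 30 virus orders of the default registry (rows of the packaged
#: host-distribution fixture, largest first)
ORDER_REGISTRY = (
    "Ortervirales",
    "Picornavirales",
    "Bunyavirales",
    "Tymovirales",
    "Reovirales",
    "Amarillovirales",
    "Mononegavirales",
    "Martellivirales",
    "Nidovirales",
    "Patatavirales",
    "Ghabrivirales",
    "Durnavirales",
    "Stellavirales",
    "Tolivirales",
    "Hepelivirales",
    "Sobelivirales",
    "Blubervirales",
    "Cryppavirales",
    "Articulavirales",
    "Jingchuvirales",
    "Nodamuvirales",
    "Ourlivirales",
    "Wolframvirales",
    "Mindivirales",
    "Norzivirales",
    "Serpentovirales",
    "Muvirales",
    "Yadokarivirales",
    "Goujianvirales",
    "Timlovirales",
)


@dataclass(frozen=True)
class HostTaxonomy:
    """The fixed two-layer host label tree."""

    layer1_labels: tuple[str, ...] = LAYER1_LABELS
    layer2_labels: tuple[str, ...] = LAYER2_LABELS
    merged_mammal_label: str = MERGED_MAMMAL_LABEL

    def parent(self, label: str) -> str | None:
        """Parent of a label: layer-2 leaves hang under Chordata."""
        if label in self.layer2_labels or label == self.merged_mammal_label:
            return "Chordata"
        if label in self.layer1_labels:
            return None
        raise KeyError(f"unknown host label: {label!r}")

    def valid_layer2(self, label: str) -> bool:
        return label in self.layer2_labels or label == self.merged_mammal_label

    def validate_record(self, record: "VirusRecord") -> None:
        if record.layer1_host not in self.layer1_labels:
            raise ValueError(
                f"record {record.id!r}: unknown layer-1 host {record.layer1_host!r}"
            )
        if record.layer2_host is not None:
            if record.layer1_host != "Chordata":
                raise ValueError(
                    f"record {record.id!r}: layer-2 host requires layer-1 Chordata"
                )
            if not self.valid_layer2(record.layer2_host):
                raise ValueError(
                    f"record {record.id!r}: unknown layer-2 host {record.layer2_host!r}"
                )


def build_default_taxonomy() -> HostTaxonomy:
    """Return the fixed default host taxonomy (5 layer-1 branches, 10 leaves)."""
    return HostTaxonomy()


@dataclass(frozen=True)
class VirusRecord:
    """One reference or query virus: identity, virus taxonomy, host labels."""

    id: str
    order: str
    layer1_host: str
    layer2_host: str | None = None
    family: str | None = None
    genus: str | None = None
    sequence_length: int | None = None
    #: all layer-1 hosts listed in the metadata; >1 marks a multi-label record
    all_layer1_hosts: tuple[str, ...] = ()

    @property
    def leaf_host(self) -> str:
        """The most specific host label (layer 2 if present, else layer 1)."""
        return self.layer2_host if self.layer2_host is not None else self.layer1_host

    @property
    def is_multilabel(self) -> bool:
        return len(set(self.all_layer1_hosts)) > 1


def records_to_frame(records: Iterable[VirusRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "order": r.order,
            "family": r.family,
            "genus": r.genus,
            "host_layer1": r.layer1_host,
            "host_layer2": r.layer2_host,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["id", "order", "family", "genus", "host_layer1", "host_layer2"])


@dataclass(frozen=True)
class OrderMode:
    """Prediction mode of one virus order."""

    mode: str  # direct_assign | layer1_only | two_layer
    direct_label: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"direct_assign", "layer1_only", "two_layer"}:
            raise ValueError(f"invalid mode {self.mode!r}")
        if (self.mode == "direct_assign") != (self.direct_label is not None):
            raise ValueError("direct_label present iff mode == direct_assign")


@dataclass
class ScreeningReport:
    """Per-order bookkeeping of the label-screening pass."""

    per_order: dict[str, dict] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.per_order, orient="index")


def screen_labels(
    records: Sequence[VirusRecord],
    min_order_size: int = 30,
    min_label_count: int = 10,
    mammal_merge_threshold: int = 50,
    taxonomy: HostTaxonomy | None = None,
) -> tuple[list[VirusRecord], ScreeningReport]:
    """Screen reference host labels order by order.

    Order of operations (documented design choice): multi-label records are
    removed first, then mammalian layer-2 labels are merged where mammalian
    records are scarcer than ``mammal_merge_threshold``, then host labels with
    fewer than ``min_label_count`` members are dropped in orders larger than
    ``min_order_size``.  Merging before filtering lets a merged ``Mammalia``
    group clear the count threshold that its separate classes would fail.
    Orders of at most ``min_order_size`` records keep all labels and are
    flagged ``small`` in the report.
    """
    taxonomy = taxonomy or build_default_taxonomy()
    for rec in records:
        taxonomy.validate_record(rec)
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)

    report = ScreeningReport()
    kept: list[VirusRecord] = []
    by_order: dict[str, list[VirusRecord]] = {}
    for rec in records:
        by_order.setdefault(rec.order, []).append(rec)

    for order, recs in by_order.items():
        entry = {
            "n_input": len(recs),
            "n_multilabel_removed": 0,
            "n_mammal_merged": 0,
            "n_label_dropped": 0,
            "small": False,
        }
        recs = [r for r in recs if not r.is_multilabel]
        entry["n_multilabel_removed"] = entry["n_input"] - len(recs)

        # mammal merge: collapse mammalian layer-2 classes when scarce
        n_mammal = sum(1 for r in recs if r.layer2_host in MAMMAL_LAYER2_LABELS)
        if 0 < n_mammal < mammal_merge_threshold:
            merged = []
            for r in recs:
                if r.layer2_host in MAMMAL_LAYER2_LABELS:
                    merged.append(replace(r, layer2_host=taxonomy.merged_mammal_label))
                    entry["n_mammal_merged"] += 1
                else:
                    merged.append(r)
            recs = merged

        # label-count filter only in orders containing more than min_order_size
        if len(recs) > min_order_size:
            leaf_counts = Counter(r.leaf_host for r in recs)
            l1_counts = Counter(r.layer1_host for r in recs)
            kept_recs = []
            for r in recs:
                # a record survives if its layer-appropriate label is frequent
                # enough: leaf count for layer-2-annotated records, layer-1
                # count otherwise
                count = leaf_counts[r.leaf_host] if r.layer2_host else l1_counts[r.layer1_host]
                if count >= min_label_count:
                    kept_recs.append(r)
                else:
                    entry["n_label_dropped"] += 1
            recs = kept_recs
        else:
            entry["small"] = True

        entry["n_output"] = len(recs)
        report.per_order[order] = entry
        kept.extend(recs)

    return kept, report


def order_mode(records_of_one_order: Sequence[VirusRecord]) -> OrderMode:
    """Decide the prediction mode of one (already screened) virus order.

    ``direct_assign`` when every record carries the same leaf host label;
    ``two_layer`` when any layer-2 annotation is present (a single distinct
    layer-2 label simply degrades the second layer to direct assignment);
    ``layer1_only`` otherwise.
    """
    if not records_of_one_order:
        raise ValueError("order_mode: empty record list")
    orders = {r.order for r in records_of_one_order}
    if len(orders) > 1:
        raise ValueError(f"order_mode: records span multiple orders {sorted(orders)}")
    leaves = {r.leaf_host for r in records_of_one_order}
    if len(leaves) == 1:
        return OrderMode("direct_assign", direct_label=next(iter(leaves)))
    if any(r.layer2_host is not None for r in records_of_one_order):
        return OrderMode("two_layer")
    return OrderMode("layer1_only")


def host_homogeneity(
    records_of_one_family: Sequence[VirusRecord],
    taxonomy: HostTaxonomy | None = None,
) -> float:
    """Fraction ``r`` of a family's members carrying its dominant layer-1 host.

    Ties in the dominant label are broken by the taxonomy's fixed layer-1
    ordering, which only matters for determinism; the returned fraction is the
    same for every tied label.
    """
    if not records_of_one_family:
        raise ValueError("host_homogeneity: empty record list")
    taxonomy = taxonomy or build_default_taxonomy()
    counts = Counter(r.layer1_host for r in records_of_one_family)
    dominant = dominant_label(counts, taxonomy.layer1_labels)
    return counts[dominant] / len(records_of_one_family)


def dominant_label(counts: Counter, label_order: Sequence[str] = ()) -> str:
    """Most frequent label; ties broken by a fixed label ordering."""
    if not counts:
        raise ValueError("dominant_label: empty counts")
    rank = {lab: i for i, lab in enumerate(label_order)}
    return max(counts, key=lambda lab: (counts[lab], -rank.get(lab, len(rank))))


# ---------------------------------------------------------------------------
# packaged host-distribution fixture


def load_host_distribution() -> pd.DataFrame:
    """Load the packaged per-order host-distribution table.

    One row per virus order of the default registry: total count ``n`` and the
    percentage of members infecting each layer-1 and layer-2 host (the merged
    ``Mammalia`` column covers orders whose mammalian classes were collapsed).
    """
    with resources.files("virhost").joinpath("data/host_distribution.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def expand_distribution_to_records(df: pd.DataFrame | None = None) -> list[VirusRecord]:
    """Expand the host-distribution table into pseudo-records.

    Percentages are converted to integer counts by largest-remainder rounding
    so each order's pseudo-records sum exactly to its printed total.  Family
    and genus are not part of the table and stay unset.
    """
    if df is None:
        df = load_host_distribution()
    l2_cols = list(LAYER2_LABELS) + [MERGED_MAMMAL_LABEL]
    records: list[VirusRecord] = []
    for _, row in df.iterrows():
        order, total = row["order"], int(row["n"])
        # leaf-level percentage per label: layer-2 labels replace their share
        # of Chordata; non-Chordata layer-1 labels stay as-is
        pct: dict[tuple[str, str | None], float] = {}
        l2_total = 0.0
        for col in l2_cols:
            v = row.get(col)
            if pd.notna(v) and v > 0:
                pct[("Chordata", col)] = float(v)
                l2_total += float(v)
        for col in LAYER1_LABELS:
            v = row.get(col)
            if pd.notna(v) and v > 0:
                if col == "Chordata":
                    rem = float(v) - l2_total
                    if rem > 0.05:  # unannotated Chordata remainder
                        pct[("Chordata", None)] = rem
                else:
                    pct[(col, None)] = float(v)
        if not pct:
            raise ValueError(f"order {order}: empty distribution row")
        counts = _largest_remainder(pct, total)
        i = 0
        for (l1, l2), c in counts.items():
            for _ in range(c):
                records.append(
                    VirusRecord(id=f"{order}_{i:05d}", order=order, layer1_host=l1, layer2_host=l2)
                )
                i += 1
    return records


def _largest_remainder(pct: dict, total: int) -> dict:
    """Allocate ``total`` among keys proportional to percentages, exactly."""
    raw = {k: total * v / 100.0 for k, v in pct.items()}
    counts = {k: int(v) for k, v in raw.items()}
    short = total - sum(counts.values())
    if short < 0:
        raise ValueError("percentages exceed 100")
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    # a label printed with a nonzero percentage always yields >= 1 record
    for k in counts:
        if counts[k] == 0:
            donor = max(counts, key=counts.get)
            counts[donor] -= 1
            counts[k] = 1
    return counts
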