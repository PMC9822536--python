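"""Aggregate ordered drug-regimen sequences into a hierarchical count tree.

The tree backs sunburst visualizations of treatment trajectories: ring k of
the sunburst is the k-th regimen, so each node counts the treated diagnoses
whose regimen sequence begins with that node's path.  Sequences are built
per (patient, diagnosis) from *all* of the diagnosis's regimens in the full
release — not only the regimens that qualified the diagnosis into the
cohort — ordered by line of therapy and truncated at a maximum depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import AnalyticCohort, assign_regimen_order, canonical_regimen_label, parse_drug_set

__all__ = [
    "TrajectoryTree",
    "build_trajectories",
    "export_sunburst_sequences",
    "import_sunburst_sequences",
]


@dataclass
class TrajectoryTree:
    """Prefix counts over regimen sequences.

    ``counts`` maps a path (tuple of canonical regimen labels) to the number
    of sequences having that path as a prefix.  ``n_contributing`` is the
    number of (patient, diagnosis) units with at least one regimen;
    ``n_excluded`` counts cohort diagnoses with no regimen at all, which do
    not appear in the tree.
    """

    counts: dict[tuple[str, ...], int] = field(default_factory=dict)
    n_contributing: int = 0
    n_excluded: int = 0

    def add_sequence(self, labels: tuple[str, ...]) -> None:
        for k in range(1, len(labels) + 1):
            prefix = labels[:k]
            self.counts[prefix] = self.counts.get(prefix, 0) + 1
        if labels:
            self.n_contributing += 1

    def depth(self) -> int:
        return max((len(p) for p in self.counts), default=0)

    def ring_total(self, depth: int) -> int:
        return sum(c for p, c in self.counts.items() if len(p) == depth)

    def children(self, path: tuple[str, ...]) -> dict[tuple[str, ...], int]:
        k = len(path) + 1
        return {
            p: c for p, c in self.counts.items() if len(p) == k and p[: k - 1] == path
        }

    def terminal_count(self, path: tuple[str, ...]) -> int:
        """Sequences that end exactly at this node (stop, no next regimen)."""
        return self.counts[path] - sum(self.children(path).values())

    def equals(self, other: "TrajectoryTree") -> bool:
        return self.counts == other.counts and self.n_contributing == other.n_contributing


def build_trajectories(
    release, cohort: AnalyticCohort, max_n_regimens: int
) -> TrajectoryTree:
    """Count regimen-sequence prefixes for the cohort's diagnoses.

    For each (record_id, ca_seq) in the cohort, all regimens of that
    diagnosis are taken from the full release, ordered within the cancer,
    truncated to ``max_n_regimens`` and labeled canonically; the tree holds
    prefix counts over these sequences.
    """
    if max_n_regimens < 1:
        raise ValueError("max_n_regimens must be >= 1")
    drugs = assign_regimen_order(release.tables["ca_drugs"])
    dx_keys = set(
        map(tuple, cohort.cohort_ca_dx[["record_id", "ca_seq"]].itertuples(index=False))
    )
    mask = pd.Series(
        [k in dx_keys for k in zip(drugs["record_id"], drugs["ca_seq"])],
        index=drugs.index,
        dtype=bool,
    )
    drugs = drugs.loc[mask]
    drugs = drugs.sort_values(
        ["record_id", "ca_seq", "order_within_cancer"], kind="stable"
    )

    tree = TrajectoryTree()
    seen: set[tuple] = set()
    for key, group in drugs.groupby(["record_id", "ca_seq"], sort=True):
        labels = tuple(
            canonical_regimen_label(parse_drug_set(s))
            for s in group["regimen_drugs"].head(max_n_regimens)
        )
        tree.add_sequence(labels)
        seen.add(key)
    tree.n_excluded = len(dx_keys - seen)
    return tree


# --------------------------------------------------------------------------
# Sequence export (the standard input convention of sunburst builders)
# --------------------------------------------------------------------------


def _escape(label: str, sep: str, esc: str) -> str:
    return label.replace(esc, esc + esc).replace(sep, esc + sep)


def _split_escaped(path_str: str, sep: str, esc: str) -> tuple[str, ...]:
    parts, cur, i = [], [], 0
    while i < len(path_str):
        ch = path_str[i]
        if ch == esc and i + 1 < len(path_str):
            cur.append(path_str[i + 1])
            i += 2
        elif ch == sep:
            parts.append("".join(cur))
            cur = []
            i += 1
        else:
            cur.append(ch)
            i += 1
    parts.append("".join(cur))
    return tuple(parts)


def export_sunburst_sequences(
    tree: TrajectoryTree, sep: str = "-", esc: str = "\\"
) -> pd.DataFrame:
    """Flatten a tree to (path string, terminal count) records.

    Each row is a complete observed sequence (joined by ``sep``; separator
    characters inside labels are escaped with ``esc``) with the number of
    units whose trajectory ended exactly there.  The export is lossless:
    re-importing it rebuilds an equal tree.
    """
    rows = []
    for path in sorted(tree.counts):
        terminal = tree.terminal_count(path)
        if terminal > 0:
            rows.append(
                {
                    "sequence": sep.join(_escape(l, sep, esc) for l in path),
                    "count": terminal,
                }
            )
    return pd.DataFrame(rows, columns=["sequence", "count"])


def import_sunburst_sequences(
    records: pd.DataFrame, sep: str = "-", esc: str = "\\"
) -> TrajectoryTree:
    """Rebuild a trajectory tree from exported (sequence, count) records."""
    tree = TrajectoryTree()
    for row in records.to_dict("records"):
        path = _split_escaped(row["sequence"], sep, esc)
        for _ in range(int(row["count"])):
            tree.add_sequence(path)
    return tree
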