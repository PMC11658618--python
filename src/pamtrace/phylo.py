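"""Sample trees from binary PAM presence matrices.

Distances are raw Hamming counts over sites where neither sample is
no_coverage (pairwise deletion). Clustering is classic UPGMA with
size-weighted average linkage and deterministic lexicographic tie-breaking
by concatenated member names; node height is merge distance / 2, so the
tree is ultrametric before re-rooting. Trees are re-rooted at the primary
sample with the fewest unique PAMs, mirroring how a founder-most primary
anchors the case lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from skbio import TreeNode

from .model import PamTraceError
from .maintenance import NO_COVERAGE, PRESENT, PresenceMatrix

log = logging.getLogger(__name__)


def binary_distance(matrix: PresenceMatrix) -> pd.DataFrame:
    """Pairwise Hamming distances between sample presence columns."""
    samples = list(matrix.entries.columns)
    if len(samples) < 2:
        raise PamTraceError("need at least two samples for distances")
    present = (matrix.entries == PRESENT).to_numpy()
    covered = (matrix.entries != NO_COVERAGE).to_numpy()
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = covered[:, i] & covered[:, j]
            if not comparable.any():
                raise PamTraceError(
                    f"no comparable sites between {samples[i]!r} and {samples[j]!r}")
            d[i, j] = d[j, i] = int(
                (present[comparable, i] != present[comparable, j]).sum())
    return pd.DataFrame(d, index=samples, columns=samples)


@dataclass
class SampleTree:
    """A rooted sample tree with its Newick serialization."""

    tree: TreeNode

    @property
    def newick(self) -> str:
        buf = StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()

    @property
    def leaves(self) -> list[str]:
        return sorted(t.name for t in self.tree.tips())

    def ascii(self) -> str:
        return self.tree.ascii_art()

    @classmethod
    def from_newick(cls, text: str) -> "SampleTree":
        return cls(TreeNode.read(StringIO(text)))


def upgma(distances: pd.DataFrame) -> SampleTree:
    """UPGMA agglomeration of a symmetric distance table.

    Merges the closest pair at each step (ties broken lexicographically by
    the clusters' concatenated member names), with new-cluster distances the
    size-weighted average of the merged pair's distances.
    """
    labels = list(distances.index)
    if list(distances.columns) != labels:
        raise PamTraceError("distance table index and columns must match")
    arr = distances.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise PamTraceError("non-finite distances")
    if not np.allclose(arr, arr.T) or not np.allclose(np.diag(arr), 0.0):
        raise PamTraceError("distance table must be symmetric with zero diagonal")
    if len(labels) == 1:
        return SampleTree(TreeNode(name=labels[0]))

    # cluster state: sort key (concatenated member names), size, height, node
    clusters: dict[str, tuple[int, float, TreeNode]] = {
        name: (1, 0.0, TreeNode(name=name)) for name in labels}
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            dist[frozenset((a, labels[j]))] = float(arr[i, j])

    while len(clusters) > 1:
        best: tuple[float, str, str] | None = None
        for key, d in dist.items():
            a, b = sorted(key)
            cand = (d, a, b)
            if best is None or cand < best:
                best = cand
        d, a, b = best
        (sa, ha, na), (sb, hb, nb) = clusters[a], clusters[b]
        height = d / 2.0
        na.length = height - ha
        nb.length = height - hb
        merged_name = ",".join(sorted(a.split(",") + b.split(",")))
        node = TreeNode(children=[na, nb])
        for other in list(clusters):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((merged_name, other))] = (sa * da + sb * db) / (sa + sb)
        dist.pop(frozenset((a, b)))
        del clusters[a], clusters[b]
        clusters[merged_name] = (sa + sb, height, node)

    (_, _, root) = next(iter(clusters.values()))
    root.length = None
    return SampleTree(root)


def unique_pam_counts(matrix: PresenceMatrix, samples: list[str] | None = None,
                      ) -> dict[str, int]:
    """Number of PAMs present in a sample and in no other sample of the matrix."""
    ent = matrix.entries
    samples = samples if samples is not None else list(ent.columns)
    present = ent == PRESENT
    counts = {}
    for s in samples:
        others = [c for c in ent.columns if c != s]
        counts[s] = int((present[s] & ~present[others].any(axis=1)).sum())
    return counts


def reroot_at_primary(tree: SampleTree, matrix: PresenceMatrix) -> SampleTree:
    """Re-root on the branch leading to the primary with the fewest unique PAMs.

    With a single primary the root lands on its pendant branch; without any
    primary the tree is returned unchanged with a warning. Ties are broken
    lexicographically and logged.
    """
    primaries = [p for p in matrix.primaries
                 if p in {t.name for t in tree.tree.tips()}]
    if not primaries:
        log.warning("no primary sample in tree; returning tree un-rerooted")
        return tree
    counts = unique_pam_counts(matrix, primaries)
    best = min(counts, key=lambda s: (counts[s], s))
    ties = [s for s in primaries if counts[s] == counts[best]]
    if len(ties) > 1:
        log.info("unique-PAM tie among primaries %s; selected %r", sorted(ties), best)
    target = next(t for t in tree.tree.tips() if t.name == best)
    length = target.length if target.length is not None else 0.0
    rerooted = tree.tree.root_at(target, above=length / 2 if length else True,
                                 branch_attrs=[])
    return SampleTree(rerooted)
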