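"""Progressive-alignment orchestration.

Per subtree: schedule the internal nodes level by level; at each node excise
gappy columns from both child profiles, align the reduced profiles (tiled
DP with full-DP fallback), restore the excised columns, and apply the
resulting binary paths to the children's rows and profiles.  Subalignments
are persisted as FASTA; the merge phase then walks the skeleton tree using
profiles only, composing each subalignment's accumulated gap-insertion path,
and the final output is assembled by streaming one subalignment file at a
time.
"""

from __future__ import annotations

import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import pair_align
from .guide_tree import (
    GuideTree,
    Schedule,
    SubtreeDecomposition,
    compute_schedule,
    compute_weights,
    decompose_centroid,
    estimate_fallback_tree,
    resolve_polytomies,
)
from .pair_align import (
    AlignmentResult,
    SubstitutionScheme,
    align_with_fallback,
    default_scheme,
)
from .profile import (
    Profile,
    apply_path_to_rows,
    build_profile,
    excise_columns,
    flag_gappy_columns,
    merge_profiles,
    restore_gappy_columns,
)
from .seq_io import (
    RunConfig,
    SequenceRecord,
    load_matrix,
    read_aligned_fasta,
    read_fasta,
    parse_newick,
    write_fasta,
)

__all__ = [
    "Subalignment",
    "MergePlan",
    "align_subtree",
    "merge_subalignments",
    "finalize_output",
    "run_pipeline",
]


@dataclass
class Subalignment:
    """Complete MSA of one subtree's sequences."""

    handle: int
    rows: Dict[str, str]
    profile: Profile
    path: Optional[Path] = None

    @property
    def width(self) -> int:
        return self.profile.length


@dataclass
class MergePlan:
    """Accumulated gap-insertion path per subalignment, in output order."""

    entries: List[Tuple[int, str]]
    width: int


def _align_two_profiles(
    pA: Profile, pB: Profile, scheme: SubstitutionScheme, config: RunConfig
) -> AlignmentResult:
    """Excise gappy columns, align reduced profiles, restore the columns.

    Returns an alignment whose paths cover the *full* input profiles.
    """
    if config.gappy_threshold < 1.0:
        maskA = flag_gappy_columns(pA, config.gappy_threshold)
        maskB = flag_gappy_columns(pB, config.gappy_threshold)
        # Excising every column would leave nothing to align; keep such a
        # profile intact instead.
        if maskA.all():
            maskA[:] = False
        if maskB.all():
            maskB[:] = False
        redA, storeA = excise_columns(pA, maskA)
        redB, storeB = excise_columns(pB, maskB)
        reduced = align_with_fallback(redA, redB, scheme, config)
        return restore_gappy_columns(reduced, storeA, storeB)
    return align_with_fallback(pA, pB, scheme, config)


def align_subtree(
    subtree: GuideTree,
    records: Dict[str, str],
    weights: Dict[str, float],
    config: RunConfig,
    scheme: Optional[SubstitutionScheme] = None,
    handle: int = 0,
) -> Subalignment:
    """Progressively align the sequences of one (binary) subtree.

    Levels of the schedule are processed in order; alignments within a level
    are independent (they share no profiles) and may run concurrently
    without changing the result, though this implementation runs them
    sequentially.
    """
    if scheme is None:
        scheme = default_scheme(config.psgp_enabled)
    missing = [n for n in subtree.leaf_names() if n not in records]
    if missing:
        raise ValueError(f"no sequence for guide-tree leaves: {missing}")

    nodes = {n.node_id: n for n in subtree.preorder()}
    state: Dict[int, Tuple[Dict[str, str], Profile]] = {}
    for leaf in subtree.leaves():
        rows = {leaf.name: records[leaf.name]}
        state[leaf.node_id] = (rows, build_profile(rows, weights))

    if subtree.n_leaves == 1:
        (rows, prof) = state[subtree.leaves()[0].node_id]
        return Subalignment(handle=handle, rows=rows, profile=prof)

    schedule = compute_schedule(subtree)
    for level in sorted(schedule.levels):
        for node_id in schedule.levels[level]:
            node = nodes[node_id]
            left, right = node.children
            rowsA, pA = state.pop(left.node_id)
            rowsB, pB = state.pop(right.node_id)
            result = _align_two_profiles(pA, pB, scheme, config)
            newA = apply_path_to_rows(rowsA, result.pathA)
            newB = apply_path_to_rows(rowsB, result.pathB)
            merged_rows = {**newA, **newB}
            merged_profile = merge_profiles(pA, pB, result.pathA, result.pathB)
            state[node_id] = (merged_rows, merged_profile)

    rows, prof = state[subtree.root.node_id]
    return Subalignment(handle=handle, rows=rows, profile=prof)


def compose_paths(first: str, second: str) -> str:
    """Path composition: applying the result equals applying ``first`` then
    ``second``.  ``second`` must consume exactly len(first) columns."""
    if second.count("0") != len(first):
        raise ValueError(
            f"path composition mismatch: second consumes {second.count('0')} "
            f"columns, first produces {len(first)}"
        )
    it = iter(first)
    return "".join(next(it) if c == "0" else "1" for c in second)


def merge_subalignments(
    skeleton: GuideTree,
    subalignments: Sequence[Subalignment],
    config: RunConfig,
    scheme: Optional[SubstitutionScheme] = None,
) -> MergePlan:
    """Walk the skeleton, aligning subalignment *profiles* into one frame.

    Only profiles and accumulated binary paths are held; rows stay on disk.
    At each skeleton node the two child profiles are aligned and each
    descendant subalignment's path is composed with its side's new path.
    """
    if scheme is None:
        scheme = default_scheme(config.psgp_enabled)
    by_handle = {sub.handle: sub for sub in subalignments}

    state: Dict[int, Tuple[List[Tuple[int, str]], Profile]] = {}
    for leaf in skeleton.leaves():
        handle = int(leaf.name)
        sub = by_handle[handle]
        state[leaf.node_id] = ([(handle, "0" * sub.width)], sub.profile)

    if skeleton.n_leaves == 1:
        entries, prof = state[skeleton.leaves()[0].node_id]
        return MergePlan(entries=entries, width=prof.length)

    nodes = {n.node_id: n for n in skeleton.preorder()}
    schedule = compute_schedule(skeleton)
    for level in sorted(schedule.levels):
        for node_id in schedule.levels[level]:
            node = nodes[node_id]
            left, right = node.children
            entriesA, pA = state.pop(left.node_id)
            entriesB, pB = state.pop(right.node_id)
            result = _align_two_profiles(pA, pB, scheme, config)
            entries = [
                (h, compose_paths(p, result.pathA)) for h, p in entriesA
            ] + [(h, compose_paths(p, result.pathB)) for h, p in entriesB]
            state[node_id] = (
                entries,
                merge_profiles(pA, pB, result.pathA, result.pathB),
            )

    entries, prof = state[skeleton.root.node_id]
    entries.sort(key=lambda e: e[0])  # deterministic subtree-major order
    return MergePlan(entries=entries, width=prof.length)


def finalize_output(
    plan: MergePlan,
    subalignment_files: Dict[int, Path],
    out_path,
    wrap: int = 60,
) -> None:
    """Stream each subalignment file, insert its recorded gaps, concatenate.

    Holds at most one subalignment's rows in memory at a time.
    """
    with open(out_path, "w") as out:
        for handle, path in plan.entries:
            rows = read_aligned_fasta(subalignment_files[handle])
            adjusted = apply_path_to_rows(rows, path)
            for ident, _ in rows:  # preserve file order
                row = adjusted[ident]
                if len(row) != plan.width:
                    raise ValueError(
                        f"subalignment {handle}: row width {len(row)} != "
                        f"final width {plan.width}"
                    )
                out.write(f">{ident}\n")
                for i in range(0, len(row), wrap):
                    out.write(row[i : i + wrap] + "\n")


def run_pipeline(
    fasta_path,
    newick_path=None,
    config: Optional[RunConfig] = None,
    out_path=None,
) -> Path:
    """End-to-end alignment: FASTA (+ optional Newick) in, MSA FASTA out."""
    config = config or RunConfig()
    fasta_path = Path(fasta_path)
    out_path = Path(out_path) if out_path else fasta_path.with_suffix(".aln.fasta")

    records = read_fasta(fasta_path)
    rec_map = {r.identifier: r.residues for r in records}
    input_order = {r.identifier: i for i, r in enumerate(records)}

    if newick_path is not None:
        tree = parse_newick(Path(newick_path).read_text())
        tree_names = set(tree.leaf_names())
        seq_names = set(rec_map)
        if tree_names != seq_names:
            only_tree = sorted(tree_names - seq_names)
            only_fasta = sorted(seq_names - tree_names)
            raise ValueError(
                "guide tree and FASTA disagree: "
                f"only in tree {only_tree}; only in FASTA {only_fasta}"
            )
    else:
        tree = estimate_fallback_tree(records, seed=config.seed)

    tree = resolve_polytomies(tree, seed=config.seed)
    weights = compute_weights(tree)

    if config.matrix_path is not None:
        scheme = load_matrix(config.matrix_path)
        if config.psgp_enabled:
            scheme = SubstitutionScheme(
                s=scheme.s, gop=scheme.gop, gep=scheme.gep, psgp_enabled=True
            )
    else:
        scheme = default_scheme(config.psgp_enabled)

    n = len(records)
    m = config.max_subtree if config.max_subtree is not None else n
    decomp = decompose_centroid(tree, max(m, 1))

    workdir_obj = None
    if config.keep_intermediates:
        workdir = Path(str(out_path) + ".work")
        workdir.mkdir(parents=True, exist_ok=True)
    else:
        workdir_obj = tempfile.TemporaryDirectory(prefix="promsa_")
        workdir = Path(workdir_obj.name)

    try:
        subalignments: List[Subalignment] = []
        files: Dict[int, Path] = {}
        for idx, subtree in enumerate(decomp.subtrees):
            sub = align_subtree(
                subtree, rec_map, weights, config, scheme, handle=idx
            )
            ordered = sorted(sub.rows, key=input_order.__getitem__)
            path = workdir / f"subalignment_{idx}.fasta"
            write_fasta([(k, sub.rows[k]) for k in ordered], path, config.wrap)
            sub.path = path
            # rows no longer needed in memory
            sub.rows = {}
            files[idx] = path
            subalignments.append(sub)

        plan = merge_subalignments(decomp.skeleton, subalignments, config, scheme)
        if config.keep_intermediates:
            with open(workdir / "merge_plan.txt", "w") as fh:
                for handle, p in plan.entries:
                    fh.write(f"{handle}\t{p}\n")
        finalize_output(plan, files, out_path, config.wrap)
    finally:
        if workdir_obj is not None:
            workdir_obj.cleanup()
    return out_path
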