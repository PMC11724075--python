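"""Maximum-common-substructure mining, clustering and enrichment scoring.

The pharmacophore-discovery step of the campaign: compute the MCS of every
unordered pair of confirmed hits (RDKit FMCS; atoms compared by element,
bonds by order, ring bonds only matching ring bonds), discard fragments
below a minimum heavy-atom size, deduplicate by the canonical form of the
fragment, cluster the unique patterns in circular-fingerprint space with
k-means, and score each pattern's fold-enrichment

    fold = (h / H) / (r / R)

where h of H hit compounds and r of R reference compounds contain the
pattern as a subgraph.  A pattern absent from the reference is flagged
infinite by default; a 0.5 pseudocount on the reference count is available
behind a flag.  Enriched patterns then select analogue sub-libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS, rdFingerprintGenerator
from sklearn.cluster import KMeans

from .exceptions import DataError, PatternError
from .library import CompoundLibrary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCSConfig:
    """FMCS comparison rules and mining filters."""

    timeout_s: int = 2
    min_atoms: int = 4
    ring_matches_ring_only: bool = True


@dataclass
class MCSPattern:
    """One unique common-substructure pattern.

    ``smarts`` is the matching query; ``key`` the canonical fragment string
    used for deduplication.  ``support_pairs`` are the hit pairs whose MCS
    produced the pattern and ``support_compounds`` the hit ids matching it.
    """

    smarts: str
    key: str
    n_atoms: int
    n_bonds: int
    support_pairs: list[tuple[str, str]] = field(default_factory=list)
    support_compounds: list[str] = field(default_factory=list)

    @classmethod
    def from_smarts(cls, smarts: str) -> "MCSPattern":
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise PatternError(f"pattern {smarts!r} does not parse")
        return cls(
            smarts=smarts,
            key=smarts,
            n_atoms=q.GetNumAtoms(),
            n_bonds=q.GetNumBonds(),
        )

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise PatternError(f"pattern {self.smarts!r} does not parse")
        return q


@dataclass
class MCSClusterSet:
    """k-means partition of a pattern set with per-cluster medoids."""

    k: int
    patterns: list[MCSPattern]
    assignments: np.ndarray
    centers: list[MCSPattern]
    feature_config: dict


@dataclass
class EnrichmentResult:
    """Fold-enrichment of a pattern in the hit list vs. a reference library."""

    pattern: MCSPattern
    hit_count: int
    hit_total: int
    ref_count: int
    ref_total: int
    fold: float
    zero_reference: bool = False


def _as_pattern(pattern: MCSPattern | str) -> MCSPattern:
    return pattern if isinstance(pattern, MCSPattern) else MCSPattern.from_smarts(pattern)


def pairwise_mcs(hits: CompoundLibrary, config: MCSConfig | None = None) -> list[MCSPattern]:
    """Mine the MCS of every unordered pair of hit compounds.

    Patterns with fewer than ``config.min_atoms`` heavy atoms are discarded;
    duplicates (by canonical fragment) are merged with their pair support
    accumulated.  Pairs whose FMCS search times out are skipped and logged.
    After mining, each unique pattern's ``support_compounds`` is filled by
    matching it back against all hits.
    """
    config = config or MCSConfig()
    ids, mols = hits.parsed()
    if len(mols) < 2:
        raise DataError("need at least 2 parsable hit compounds")
    unique: dict[str, MCSPattern] = {}
    for a in range(len(mols)):
        for b in range(a + 1, len(mols)):
            res = rdFMCS.FindMCS(
                [mols[a], mols[b]],
                atomCompare=rdFMCS.AtomCompare.CompareElements,
                bondCompare=rdFMCS.BondCompare.CompareOrder,
                ringMatchesRingOnly=config.ring_matches_ring_only,
                timeout=config.timeout_s,
            )
            if res.canceled:
                logger.warning("FMCS timeout for pair (%s, %s); skipped", ids[a], ids[b])
                continue
            if res.numAtoms < config.min_atoms:
                continue
            qmol = res.queryMol
            if qmol is None:
                continue
            match = mols[a].GetSubstructMatch(qmol)
            if match:
                key = Chem.MolFragmentToSmiles(mols[a], atomsToUse=list(match), canonical=True)
            else:  # fall back to the raw query string
                key = res.smartsString
            pat = unique.get(key)
            if pat is None:
                pat = MCSPattern(
                    smarts=res.smartsString,
                    key=key,
                    n_atoms=res.numAtoms,
                    n_bonds=res.numBonds,
                )
                unique[key] = pat
            pat.support_pairs.append((ids[a], ids[b]))
    patterns = sorted(unique.values(), key=lambda p: (-p.n_atoms, p.key))
    for pat in patterns:
        q = pat.query()
        pat.support_compounds = [cid for cid, m in zip(ids, mols) if m.HasSubstructMatch(q)]
    return patterns


def fragment_to_mol(pattern: MCSPattern) -> Chem.Mol:
    """The pattern's fragment as a (possibly partially sanitized) molecule.

    Fragments of aromatic rings are not valid molecules on their own, so
    sanitization falls back to a permissive pass that keeps aromatic flags.
    """
    mol = Chem.MolFromSmiles(pattern.key)
    if mol is not None:
        return mol
    mol = Chem.MolFromSmiles(pattern.key, sanitize=False)
    if mol is None:
        mol = Chem.MolFromSmarts(pattern.smarts)
    if mol is None:
        raise PatternError(f"cannot build a fragment molecule for {pattern.key!r}")
    mol.UpdatePropertyCache(strict=False)
    Chem.SanitizeMol(
        mol,
        Chem.SanitizeFlags.SANITIZE_ALL
        ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
        ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY,
        catchErrors=True,
    )
    return mol


def _fingerprints(patterns: Sequence[MCSPattern], n_bits: int, radius: int) -> np.ndarray:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    X = np.zeros((len(patterns), n_bits), dtype=np.float64)
    for i, pat in enumerate(patterns):
        X[i] = gen.GetFingerprintAsNumPy(fragment_to_mol(pat))
    return X


def cluster_mcs(
    patterns: Sequence[MCSPattern],
    k: int = 10,
    seed: int = 0,
    n_bits: int = 1024,
    radius: int = 2,
    n_init: int = 10,
) -> MCSClusterSet:
    """k-means over pattern fragments in binary circular-fingerprint space.

    Each cluster's representative (medoid) is the member nearest its
    centroid, ties broken by input order; deterministic given the seed.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    patterns = list(patterns)
    if k > len(patterns):
        raise ValueError("k cannot exceed the number of patterns")
    X = _fingerprints(patterns, n_bits=n_bits, radius=radius)
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    labels = km.fit_predict(X)
    centers = []
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        centers.append(patterns[int(members[int(np.argmin(d))])])
    return MCSClusterSet(
        k=k,
        patterns=patterns,
        assignments=labels,
        centers=centers,
        feature_config={"n_bits": n_bits, "radius": radius, "metric": "euclidean"},
    )


def _count_matches(query: Chem.Mol, library: CompoundLibrary) -> tuple[int, int]:
    _, mols = library.parsed()
    n = sum(1 for m in mols if m.HasSubstructMatch(query))
    return n, len(mols)


def enrichment_fold(
    pattern: MCSPattern | str,
    hits: CompoundLibrary,
    reference: CompoundLibrary,
    pseudocount: bool = False,
) -> EnrichmentResult:
    """Fold-enrichment of a pattern: (h/H) / (r/R), compound-level counts.

    ``r = 0`` yields an infinite fold with ``zero_reference=True`` unless
    ``pseudocount`` replaces r with 0.5.
    """
    pat = _as_pattern(pattern)
    if len(hits) == 0 or len(reference) == 0:
        raise DataError("hit and reference libraries must be non-empty")
    q = pat.query()
    h, H = _count_matches(q, hits)
    r, R = _count_matches(q, reference)
    if H == 0 or R == 0:
        raise DataError("no parsable compounds in one of the libraries")
    zero_ref = r == 0
    r_eff = 0.5 if (zero_ref and pseudocount) else r
    fold = float("inf") if r_eff == 0 else (h / H) / (r_eff / R)
    return EnrichmentResult(
        pattern=pat,
        hit_count=h,
        hit_total=H,
        ref_count=r,
        ref_total=R,
        fold=fold,
        zero_reference=zero_ref,
    )


def select_analogues(library: CompoundLibrary, pattern: MCSPattern | str) -> CompoundLibrary:
    """Sub-library of compounds containing the pattern, ordered by id."""
    pat = _as_pattern(pattern)
    q = pat.query()
    ids, mols = library.parsed()
    keep = sorted(cid for cid, m in zip(ids, mols) if m.HasSubstructMatch(q))
    sub = library.subset(keep, provenance="candidate")
    sub.records = sub.records.sort_values("compound_id", kind="mergesort").reset_index(drop=True)
    return sub
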