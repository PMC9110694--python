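"""MS/MS library annotation with forward dot-product scoring and MSI levels.

Candidate library entries are gated by a precursor m/z window (±15 ppm) and,
when the library entry has a retention time (in-house entries), a mode-
specific RT window (±30 s HILIC, ±20 s RPLC). Similarity is the forward
dot-product: fragments are greedily paired one-to-one within a ppm tolerance
(closest m/z first), intensities are weighted (square root by default), and

    score = (sum of paired w_q * w_r)^2 / (sum w_q^2 * sum w_r^2)

so identical spectra score 1 (Cauchy-Schwarz) and unmatched fragments only
inflate the denominator. Annotations with score >= 0.4 are reported at MSI
level 1 (in-house: m/z + RT + fragments) or level 2 (public spectral match);
failing or absent matches fall to level 4 (unknown); level 3 (putative) is a
caller-supplied designation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "MatchConfig",
    "MatchResult",
    "candidate_search",
    "forward_dot_product",
    "annotate_features",
    "read_spectra",
    "write_msp",
]


@dataclass
class Spectrum:
    """Centroided MS/MS spectrum with precursor m/z and optional RT."""

    precursor_mz: float
    fragments: list[tuple[float, float]]  # (m/z, intensity >= 0), sorted by m/z
    rt: float | None = None  # seconds
    mode: str = "HILIC"  # HILIC or RPLC
    polarity: str = "positive"
    identifier: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        frags = sorted((float(m), float(i)) for m, i in self.fragments)
        if any(i < 0 for _, i in frags):
            raise ValueError("fragment intensities must be non-negative")
        self.fragments = frags

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.fragments])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.fragments])


@dataclass
class MatchConfig:
    precursor_ppm: float = 15.0
    rt_window_s: dict = field(default_factory=lambda: {"HILIC": 30.0, "RPLC": 20.0})
    fragment_ppm: float = 15.0
    score_min: float = 0.4
    intensity_power: float = 0.5
    #: "greedy" (closest m/z first, default) or "optimal" (max-weight assignment)
    pairing: str = "greedy"

    def validate(self) -> None:
        if self.pairing not in ("greedy", "optimal"):
            raise ValueError("pairing must be 'greedy' or 'optimal'")
        if self.precursor_ppm <= 0 or self.fragment_ppm <= 0:
            raise ValueError("ppm windows must be positive")
        if any(v <= 0 for v in self.rt_window_s.values()):
            raise ValueError("RT windows must be positive")
        if not 0.0 <= self.score_min <= 1.0:
            raise ValueError("score_min must lie in [0, 1]")


@dataclass
class MatchResult:
    feature_id: str
    library_id: str | None
    score: float
    msi_level: int
    n_matched_fragments: int
    source: str = "none"  # inhouse | public | none


def candidate_search(query: Spectrum, library: list[Spectrum],
                     cfg: MatchConfig | None = None) -> list[Spectrum]:
    """Library entries within the precursor ppm window and, where the entry
    has an RT, the mode's RT window (public entries without RT skip the RT
    gate)."""
    cfg = cfg or MatchConfig()
    cfg.validate()
    out = []
    for entry in library:
        dppm = abs(query.precursor_mz - entry.precursor_mz) / entry.precursor_mz * 1e6
        if dppm > cfg.precursor_ppm:
            continue
        if entry.rt is not None and query.rt is not None:
            window = cfg.rt_window_s.get(query.mode, max(cfg.rt_window_s.values()))
            if abs(query.rt - entry.rt) > window:
                continue
        out.append(entry)
    return out


def _pair_fragments(
    q_mz: np.ndarray, r_mz: np.ndarray, ppm: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one pairing, closest m/z difference first."""
    cand = []
    for i, mq in enumerate(q_mz):
        for j, mr in enumerate(r_mz):
            if abs(mq - mr) / mr * 1e6 <= ppm:
                cand.append((abs(mq - mr), i, j))
    cand.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_q or j in used_r:
            continue
        used_q.add(i)
        used_r.add(j)
        pairs.append((i, j))
    return pairs


def _pair_fragments_optimal(
    q_mz: np.ndarray, r_mz: np.ndarray, wq: np.ndarray, wr: np.ndarray, ppm: float
) -> list[tuple[int, int]]:
    """One-to-one pairing maximizing the summed weight product."""
    from scipy.optimize import linear_sum_assignment

    gain = np.zeros((len(q_mz), len(r_mz)))
    for i, mq in enumerate(q_mz):
        for j, mr in enumerate(r_mz):
            if abs(mq - mr) / mr * 1e6 <= ppm:
                gain[i, j] = wq[i] * wr[j]
    rows, cols = linear_sum_assignment(-gain)
    return [(i, j) for i, j in zip(rows, cols) if gain[i, j] > 0]


def forward_dot_product(query: Spectrum, reference: Spectrum,
                        cfg: MatchConfig | None = None) -> tuple[float, int]:
    """Forward dot-product similarity in [0, 1] and the matched-fragment count."""
    cfg = cfg or MatchConfig()
    cfg.validate()
    if not query.fragments or not reference.fragments:
        raise ValueError("both spectra must have at least one fragment")
    wq = query.intensity ** cfg.intensity_power
    wr = reference.intensity ** cfg.intensity_power
    if cfg.pairing == "optimal":
        pairs = _pair_fragments_optimal(query.mz, reference.mz, wq, wr, cfg.fragment_ppm)
    else:
        pairs = _pair_fragments(query.mz, reference.mz, cfg.fragment_ppm)
    num = sum(wq[i] * wr[j] for i, j in pairs) ** 2
    den = float((wq**2).sum() * (wr**2).sum())
    score = 0.0 if den == 0 else float(num / den)
    return min(score, 1.0), len(pairs)


def annotate_features(
    features: list[str],
    spectra_map: dict[str, list[Spectrum]],
    inhouse_library: list[Spectrum],
    public_library: list[Spectrum],
    cfg: MatchConfig | None = None,
    putative: dict[str, str] | None = None,
) -> list[MatchResult]:
    """Best-scoring annotation per feature across all its MS/MS spectra.

    In-house matches (precursor m/z + RT + fragments) give MSI level 1,
    public spectral matches level 2; scores below ``score_min`` are demoted
    to level 4 (unknown). ``putative`` names caller-assigned level-3
    identities for otherwise unmatched features.
    """
    cfg = cfg or MatchConfig()
    cfg.validate()
    putative = putative or {}
    results = []
    for fid in features:
        best: tuple[float, int, str | None, str] = (0.0, 0, None, "none")
        for spec in spectra_map.get(fid, []):
            for source, library in (("inhouse", inhouse_library), ("public", public_library)):
                for entry in candidate_search(spec, library, cfg):
                    score, n_matched = forward_dot_product(spec, entry, cfg)
                    if score > best[0]:
                        best = (score, n_matched, entry.identifier, source)
        score, n_matched, lib_id, source = best
        if score >= cfg.score_min and lib_id is not None:
            level = 1 if source == "inhouse" else 2
        elif fid in putative:
            lib_id, level, source = putative[fid], 3, "putative"
        else:
            lib_id, level, source = None, 4, "none"
        results.append(
            MatchResult(feature_id=fid, library_id=lib_id, score=round(score, 6),
                        msi_level=level, n_matched_fragments=n_matched, source=source)
        )
    return results


# ---------------------------------------------------------------------------
# MSP / MGF plumbing (via matchms)


def _from_matchms(ms_spectrum, default_mode: str = "HILIC") -> Spectrum:
    md = ms_spectrum.metadata
    rt = md.get("retention_time")
    return Spectrum(
        precursor_mz=float(md.get("precursor_mz")),
        fragments=list(zip(ms_spectrum.peaks.mz, ms_spectrum.peaks.intensities)),
        rt=float(rt) if rt is not None else None,
        mode=str(md.get("mode", default_mode)),
        polarity=str(md.get("ionmode", "positive")),
        identifier=md.get("compound_name") or md.get("title"),
        metadata=dict(md),
    )


def read_spectra(path: str, default_mode: str = "HILIC") -> list[Spectrum]:
    """Read an MSP or MGF spectral file (format by extension)."""
    import matchms.importing as imp

    path = str(path)
    if path.lower().endswith(".msp"):
        raw = imp.load_from_msp(path, metadata_harmonization=True)
    elif path.lower().endswith(".mgf"):
        raw = imp.load_from_mgf(path, metadata_harmonization=True)
    else:
        raise ValueError(f"unsupported spectral format: {path}")
    return [_from_matchms(s, default_mode) for s in raw if s is not None]


def write_msp(spectra: list[Spectrum], path: str) -> None:
    """Write spectra as MSP text."""
    lines = []
    for s in spectra:
        lines.append(f"NAME: {s.identifier or 'unknown'}")
        lines.append(f"PRECURSORMZ: {s.precursor_mz}")
        if s.rt is not None:
            lines.append(f"RETENTIONTIME: {s.rt}")
        lines.append(f"IONMODE: {s.polarity}")
        lines.append(f"Num Peaks: {len(s.fragments)}")
        for mz, inten in s.fragments:
            lines.append(f"{mz} {inten}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
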