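"""Shared run configuration for the typing pipeline and CLI."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields


@dataclass
class RunConfig:
    """Tunable thresholds of the typing pipeline.

    window: genes examined per side of a focal candidate (6 covers every
        known per-type context determinant plus insertion slack).
    max_gap: intergenic distance (bp) still chaining co-directional genes
        into one operon-like cluster.
    motif_profile: 'strict' (literal discovered patterns) or 'generalized'
        (relaxed forms admitting the AlkB0 deviations).
    min_length: minimum protein length (aa) for a family call.
    ahcy_adjacency: genes downstream within which ahcY must sit for AlkB0.
    mana_ahcy_tolerance: unrecognized genes tolerated per side between the
        focal gene and the manA/ahcY anchors.
    gap_bounds: allowed residue spacing between consecutive signature motifs.
    """

    window: int = 6
    max_gap: int = 500
    motif_profile: str = "generalized"
    min_length: int = 300
    ahcy_adjacency: int = 2
    mana_ahcy_tolerance: int = 2
    gap_bounds: tuple[int, int] = (10, 160)
    lexicon_path: str | None = None
    seed: int | None = None
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        for name in ("window", "max_gap", "min_length", "ahcy_adjacency"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mana_ahcy_tolerance < 0:
            raise ValueError("mana_ahcy_tolerance must be >= 0")
        lo, hi = self.gap_bounds
        if not (0 <= lo <= hi):
            raise ValueError("gap_bounds must satisfy 0 <= min <= max")
        if self.motif_profile not in ("strict", "generalized"):
            raise ValueError("motif_profile must be 'strict' or 'generalized'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gap_bounds"] = list(self.gap_bounds)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "gap_bounds" in kwargs:
            kwargs["gap_bounds"] = tuple(kwargs["gap_bounds"])
        return cls(**kwargs)
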