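"""Gene panel: which (hybridization cycle, fluorophore channel) encodes each gene."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class GenePanel:
    """Maps gene names to their (cycle, channel) slot.

    Channel 0 in every cycle is reserved for the nuclear stain, so signal
    channels are >= 1.  A slot can hold at most one gene.
    """

    assignments: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        seen: dict[tuple[int, int], str] = {}
        for gene, (cy, ch) in self.assignments.items():
            if cy < 0 or ch < 1:
                raise ValueError(
                    f"gene {gene!r}: cycle must be >= 0 and channel >= 1 "
                    "(channel 0 is the nuclear stain)"
                )
            if (cy, ch) in seen:
                raise ValueError(
                    f"slot (cycle={cy}, channel={ch}) assigned to both "
                    f"{seen[(cy, ch)]!r} and {gene!r}"
                )
            seen[(cy, ch)] = gene

    @property
    def genes(self) -> list[str]:
        return list(self.assignments)

    @property
    def n_cycles(self) -> int:
        return 1 + max(cy for cy, _ in self.assignments.values())

    @property
    def n_channels(self) -> int:
        """Channels per cycle, including the nuclear channel 0."""
        return 1 + max(ch for _, ch in self.assignments.values())

    def slot(self, gene: str) -> tuple[int, int]:
        try:
            return self.assignments[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} has no (cycle, channel) assignment") from None

    @classmethod
    def from_csv(cls, path: str) -> "GenePanel":
        df = pd.read_csv(path)
        required = {"gene", "cycle", "channel"}
        if not required.issubset(df.columns):
            raise ValueError(f"panel CSV needs columns {sorted(required)}")
        return cls({r.gene: (int(r.cycle), int(r.channel)) for r in df.itertuples()})

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            [(g, cy, ch) for g, (cy, ch) in self.assignments.items()],
            columns=["gene", "cycle", "channel"],
        ).to_csv(path, index=False)
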