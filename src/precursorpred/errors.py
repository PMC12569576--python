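"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class PrecursorPredError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(PrecursorPredError):
    """Invalid configuration: bad grids, mismatched fingerprint settings, bad fractions."""


class DataError(PrecursorPredError):
    """Invalid data: schema violations, missing columns, impossible splits."""


class SmilesParseError(DataError):
    """A SMILES string failed to parse; carries the offending string."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparsable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class CycleError(DataError):
    """A pathway edge list contains a directed cycle; carries one offending cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(
            "pathway graph is not acyclic; offending cycle: "
            + " -> ".join(self.cycle + [self.cycle[0]])
        )
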