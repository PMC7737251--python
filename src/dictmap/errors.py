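"""Exception hierarchy shared by all dictmap modules.

Each subclass carries a process exit code so the command-line layer can
translate failures uniformly: 1 validation/config, 2 I/O, 3 permission,
4 illegal state transition.
"""


class DictmapError(Exception):
    """Base class for all errors raised by dictmap."""

    exit_code = 1


class SchemaError(DictmapError):
    """An input file does not have the required columns or header."""

    exit_code = 1


class ConfigError(DictmapError):
    """A configuration value is inconsistent (e.g. field not imported)."""

    exit_code = 1


class ValidationError(DictmapError):
    """Input content violates an invariant (e.g. a cycle in parent links)."""

    exit_code = 1


class CycleError(ValidationError):
    """The parent relation of an ontology contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(
            "cycle in parent relation: " + " -> ".join(self.cycle + [self.cycle[0]])
        )


class NotFoundError(DictmapError):
    """A referenced entity (concept, variable, project ...) does not exist."""

    exit_code = 1

    def __init__(self, kind: str, identifier: str):
        self.kind = kind
        self.identifier = identifier
        super().__init__(f"{kind} not found: {identifier!r}")


class InputOutputError(DictmapError):
    """A file could not be read or written."""

    exit_code = 2


class PermissionDeniedError(DictmapError):
    """The acting user lacks the privilege required by the operation."""

    exit_code = 3


class StateError(DictmapError):
    """The operation is illegal in the current mapping state."""

    exit_code = 4
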