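"""Instrumentation guarding against test-fold leakage into fit routines.

Cross-validation drivers register the held-out subject indices before any
fitting happens in a fold; every fit routine in the package (standardiser,
DAE training, RFE, classifier head) reports the indices of the rows it was
given.  Any overlap is counted as a violation, so a full CV run can assert
that no test-fold row ever reached a ``fit``.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["LeakageGuard", "guard"]


class LeakageGuard:
    def __init__(self) -> None:
        self._test_ids: frozenset | None = None
        self.n_checks = 0
        self.n_violations = 0
        self.violations: list[dict] = []

    def reset(self) -> None:
        self._test_ids = None
        self.n_checks = 0
        self.n_violations = 0
        self.violations = []

    @contextmanager
    def protect(self, test_ids):
        """Mark ``test_ids`` as off-limits to fitting for the enclosed block."""
        previous = self._test_ids
        self._test_ids = frozenset(np.asarray(list(test_ids)).tolist())
        try:
            yield self
        finally:
            self._test_ids = previous

    def check_fit(self, row_ids, what: str = "fit") -> None:
        """Called by fit routines with the ids of the rows they were given."""
        self.n_checks += 1
        if self._test_ids is None or row_ids is None:
            return
        overlap = self._test_ids.intersection(np.asarray(list(row_ids)).tolist())
        if overlap:
            self.n_violations += 1
            self.violations.append({"what": what, "ids": sorted(overlap)})


#: Process-wide guard used by the built-in CV drivers.
guard = LeakageGuard()
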