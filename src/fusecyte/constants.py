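"""Shared label vocabulary.

Class order is alphabetical and fixed; every label vector, confusion matrix
and weight vector in the package is indexed in this order.
"""

CLASSES: tuple[str, ...] = ("astrocyte", "cortical", "shsy5y")
CLASS_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}
N_CLASSES: int = len(CLASSES)
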