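"""Recompute published benchmark metrics from their confusion counts.

The published evaluation reports both headline percentages and the raw error
counts; Accuracy, Precision, Recall and F1 follow from the counts alone, so
the table below checks the arithmetic.  One reported recall is internally
inconsistent with its counts and is flagged rather than matched.
"""

from histomorph import format_table

print(format_table())
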