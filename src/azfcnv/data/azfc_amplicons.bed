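# Simplified AZFc ampliconic architecture, chrY (GRCh38-like coordinates).
# Columns: contig, start, end, class_id (0-based half-open).
# Amplicon classes carry their conventional color names; ir1/ir2 are
# inverted-repeat elements; ctrl is a single-copy X-degenerate control
# region used for depth normalization.  Editable configuration: interval
# boundaries are deliberately simplified and may be replaced wholesale.
chrY	14500000	14600000	ctrl
chrY	23600000	23700000	ir1
chrY	23720000	23940000	teal
chrY	23960000	24080000	blue
chrY	24080000	24300000	teal
chrY	24320000	24440000	blue
chrY	24460000	24610000	green
chrY	24630000	24740000	red
chrY	24760000	24850000	gray
chrY	24880000	24990000	red
chrY	25010000	25100000	gray
chrY	25130000	25280000	green
chrY	25300000	25410000	yellow
chrY	25430000	25500000	ir2
chrY	25560000	25670000	red
chrY	25720000	25840000	blue
chrY	25880000	25950000	ir2
chrY	25960000	26070000	red
chrY	26100000	26250000	green
chrY	26260000	26370000	yellow
chrY	26380000	26500000	blue
chrY	26500000	26600000	ir1
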