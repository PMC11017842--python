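# Nearest-neighbor RNA/RNA duplex parameters, delta-G at 37 C in kcal/mol.
# Stack rows are keyed by the target-strand (UTR, 5'->3') dinucleotide of two
# consecutive Watson-Crick pairs; the partner strand is its complement read
# 3'->5'.  Values follow the standard Watson-Crick nearest-neighbor set; the
# table is symmetric under reverse complement of the key.
# Non-stack rows parameterise the rest of the additive model:
#   initiation  - duplex initiation penalty (reduced-scale; see docs/methods.md)
#   wobble_stack - flat term for any stack involving a G:U wobble pair
#   loop_open / loop_per_nt - linear penalty for an internal loop or bulge:
#       loop_open + loop_per_nt * (number of unpaired nucleotides in the loop)
key	delta_g
AA	-0.93
AU	-1.10
AC	-2.24
AG	-2.08
CA	-2.11
CC	-3.26
CG	-2.36
CU	-2.08
GA	-2.35
GC	-3.42
GG	-3.26
GU	-2.24
UA	-1.33
UC	-2.35
UG	-2.11
UU	-0.93
initiation	0.50
wobble_stack	-0.50
loop_open	0.80
loop_per_nt	0.40
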