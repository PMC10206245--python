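# Nearest-neighbor free-energy parameters for intermolecular RNA:RNA
# duplexes at 37 C, in kcal/mol (Turner 2004 rule set).
#
# stack <pair1> <pair2> <dG>
#   Energy of two adjacent base pairs read 5'->3' on the top strand:
#   pair1 = (top_i, bottom_j), pair2 = (top_i+1, bottom_j-1).
#   Pair symbols give top then bottom nucleotide (e.g. GU = G on the top
#   strand paired with U on the bottom). The table is symmetric under
#   reading the duplex from the opposite strand.
# bulge <len> <dG>        bulge-loop initiation, len unpaired on one side
# internal <len> <dG>     internal-loop initiation, len = total unpaired
# ninio <per_nt> <max>    internal-loop asymmetry penalty (|a-b| scaled)
# init <dG>               duplex initiation, applied once per duplex
stack CG CG -2.40
stack CG GC -3.30
stack CG GU -2.10
stack CG UG -1.40
stack CG AU -2.10
stack CG UA -2.10
stack GC CG -3.30
stack GC GC -3.40
stack GC GU -2.50
stack GC UG -1.50
stack GC AU -2.20
stack GC UA -2.40
stack GU CG -2.10
stack GU GC -2.50
stack GU GU 1.30
stack GU UG -0.50
stack GU AU -1.40
stack GU UA -1.30
stack UG CG -1.40
stack UG GC -1.50
stack UG GU -0.50
stack UG UG 0.30
stack UG AU -0.60
stack UG UA -1.00
stack AU CG -2.10
stack AU GC -2.20
stack AU GU -1.40
stack AU UG -0.60
stack AU AU -1.10
stack AU UA -0.90
stack UA CG -2.10
stack UA GC -2.40
stack UA GU -1.30
stack UA UG -1.00
stack UA AU -0.90
stack UA UA -1.30
bulge 1 3.80
bulge 2 2.80
bulge 3 3.20
bulge 4 3.60
bulge 5 4.00
bulge 6 4.40
bulge 7 4.60
bulge 8 4.70
bulge 9 4.80
bulge 10 4.90
bulge 11 5.00
bulge 12 5.10
bulge 13 5.20
bulge 14 5.30
bulge 15 5.40
internal 2 1.00
internal 3 1.00
internal 4 1.10
internal 5 2.00
internal 6 2.00
internal 7 2.10
internal 8 2.30
internal 9 2.40
internal 10 2.50
internal 11 2.60
internal 12 2.70
internal 13 2.80
internal 14 2.90
internal 15 2.90
ninio 0.60 3.00
init 4.10
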