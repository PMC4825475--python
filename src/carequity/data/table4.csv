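location,age,vis_gp,ses,vis_sd,count
peripheral,ge60,yes,low,yes,17
peripheral,ge60,yes,low,no,102
peripheral,ge60,yes,middle,yes,6
peripheral,ge60,yes,middle,no,42
peripheral,ge60,yes,high,yes,2
peripheral,ge60,yes,high,no,9
peripheral,ge60,no,low,yes,21
peripheral,ge60,no,low,no,159
peripheral,ge60,no,middle,yes,16
peripheral,ge60,no,middle,no,97
peripheral,ge60,no,high,yes,8
peripheral,ge60,no,high,no,55
peripheral,lt60,yes,low,yes,16
peripheral,lt60,yes,low,no,236
peripheral,lt60,yes,middle,yes,11
peripheral,lt60,yes,middle,no,100
peripheral,lt60,yes,high,yes,6
peripheral,lt60,yes,high,no,58
peripheral,lt60,no,low,yes,51
peripheral,lt60,no,low,no,1926
peripheral,lt60,no,middle,yes,53
peripheral,lt60,no,middle,no,1028
peripheral,lt60,no,high,yes,36
peripheral,lt60,no,high,no,517
intermediate,ge60,yes,low,yes,20
intermediate,ge60,yes,low,no,120
intermediate,ge60,yes,middle,yes,25
intermediate,ge60,yes,middle,no,140
intermediate,ge60,yes,high,yes,10
intermediate,ge60,yes,high,no,38
intermediate,ge60,no,low,yes,34
intermediate,ge60,no,low,no,292
intermediate,ge60,no,middle,yes,42
intermediate,ge60,no,middle,no,316
intermediate,ge60,no,high,yes,18
intermediate,ge60,no,high,no,165
intermediate,lt60,yes,low,yes,21
intermediate,lt60,yes,low,no,300
intermediate,lt60,yes,middle,yes,37
intermediate,lt60,yes,middle,no,234
intermediate,lt60,yes,high,yes,13
intermediate,lt60,yes,high,no,184
intermediate,lt60,no,low,yes,61
intermediate,lt60,no,low,no,2659
intermediate,lt60,no,middle,yes,96
intermediate,lt60,no,middle,no,2332
intermediate,lt60,no,high,yes,86
intermediate,lt60,no,high,no,1654
central,ge60,yes,low,yes,51
central,ge60,yes,low,no,219
central,ge60,yes,middle,yes,55
central,ge60,yes,middle,no,259
central,ge60,yes,high,yes,30
central,ge60,yes,high,no,155
central,ge60,no,low,yes,58
central,ge60,no,low,no,443
central,ge60,no,middle,yes,84
central,ge60,no,middle,no,623
central,ge60,no,high,yes,71
central,ge60,no,high,no,538
central,lt60,yes,low,yes,20
central,lt60,yes,low,no,315
central,lt60,yes,middle,yes,37
central,lt60,yes,middle,no,370
central,lt60,yes,high,yes,56
central,lt60,yes,high,no,574
central,lt60,no,low,yes,96
central,lt60,no,low,no,2892
central,lt60,no,middle,yes,146
central,lt60,no,middle,no,3249
central,lt60,no,high,yes,334
central,lt60,no,high,no,4824
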