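year,age_band,population
2010,15+,1123000
2011,15+,1115000
2012,15+,1108000
2013,15+,1103000
2014,15+,1098000
2015,15+,1094000
2010,15-44,540000
2011,15-44,532000
2012,15-44,524000
2013,15-44,516000
2014,15-44,508000
2015,15-44,500000
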