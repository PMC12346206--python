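year,rate
2015,2.7197
2016,3.0181
2017,3.6479
2018,4.8301
2019,5.6747
2020,7.0089
2021,8.8504
2022,16.5490
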