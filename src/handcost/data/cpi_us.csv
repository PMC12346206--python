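period,index
2015,237.017
2016,240.007
2017,245.120
2018,251.107
2019,255.657
2020,258.811
2021,270.970
2022,292.655
2022Q4,297.987
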