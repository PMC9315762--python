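# Published treatment x year mean season metrics for the 12-tree soil-warming
# experiment (2010-2021). year = "mean" rows are the published Means column.
# cessation_q10 / cessation_q20 (90% / 80% completion) overall means are
# published only as headline values, so only their "mean" rows exist.
metric,group,year,value
onset_q05,control,2010,147
onset_q05,control,2011,155
onset_q05,control,2012,147
onset_q05,control,2013,140
onset_q05,control,2014,149
onset_q05,control,2015,149
onset_q05,control,2016,155
onset_q05,control,2017,156
onset_q05,control,2018,157
onset_q05,control,2019,164
onset_q05,control,2020,157
onset_q05,control,2021,146
onset_q05,control,mean,151
onset_q05,heated,2010,145
onset_q05,heated,2011,160
onset_q05,heated,2012,148
onset_q05,heated,2013,146
onset_q05,heated,2014,157
onset_q05,heated,2015,148
onset_q05,heated,2016,153
onset_q05,heated,2017,153
onset_q05,heated,2018,154
onset_q05,heated,2019,162
onset_q05,heated,2020,155
onset_q05,heated,2021,145
onset_q05,heated,mean,152
onset_q05,overall,2010,146
onset_q05,overall,2011,157
onset_q05,overall,2012,147
onset_q05,overall,2013,142
onset_q05,overall,2014,152
onset_q05,overall,2015,149
onset_q05,overall,2016,154
onset_q05,overall,2017,155
onset_q05,overall,2018,156
onset_q05,overall,2019,163
onset_q05,overall,2020,156
onset_q05,overall,2021,146
onset_q05,overall,mean,152
cessation_q05,control,2010,249
cessation_q05,control,2011,232
cessation_q05,control,2012,236
cessation_q05,control,2013,241
cessation_q05,control,2014,273
cessation_q05,control,2015,241
cessation_q05,control,2016,264
cessation_q05,control,2017,248
cessation_q05,control,2018,294
cessation_q05,control,2019,259
cessation_q05,control,2020,242
cessation_q05,control,2021,214
cessation_q05,control,mean,248
cessation_q05,heated,2010,254
cessation_q05,heated,2011,232
cessation_q05,heated,2012,242
cessation_q05,heated,2013,242
cessation_q05,heated,2014,261
cessation_q05,heated,2015,226
cessation_q05,heated,2016,268
cessation_q05,heated,2017,223
cessation_q05,heated,2018,234
cessation_q05,heated,2019,242
cessation_q05,heated,2020,232
cessation_q05,heated,2021,206
cessation_q05,heated,mean,240
cessation_q05,overall,2010,252
cessation_q05,overall,2011,232
cessation_q05,overall,2012,239
cessation_q05,overall,2013,242
cessation_q05,overall,2014,268
cessation_q05,overall,2015,235
cessation_q05,overall,2016,266
cessation_q05,overall,2017,237
cessation_q05,overall,2018,270
cessation_q05,overall,2019,252
cessation_q05,overall,2020,238
cessation_q05,overall,2021,211
cessation_q05,overall,mean,244
duration_q05,control,2010,102
duration_q05,control,2011,77
duration_q05,control,2012,89
duration_q05,control,2013,102
duration_q05,control,2014,124
duration_q05,control,2015,92
duration_q05,control,2016,109
duration_q05,control,2017,92
duration_q05,control,2018,137
duration_q05,control,2019,95
duration_q05,control,2020,85
duration_q05,control,2021,68
duration_q05,control,mean,96
duration_q05,heated,2010,109
duration_q05,heated,2011,72
duration_q05,heated,2012,95
duration_q05,heated,2013,96
duration_q05,heated,2014,104
duration_q05,heated,2015,77
duration_q05,heated,2016,116
duration_q05,heated,2017,71
duration_q05,heated,2018,80
duration_q05,heated,2019,80
duration_q05,heated,2020,76
duration_q05,heated,2021,61
duration_q05,heated,mean,88
duration_q05,overall,2010,106
duration_q05,overall,2011,75
duration_q05,overall,2012,92
duration_q05,overall,2013,99
duration_q05,overall,2014,116
duration_q05,overall,2015,86
duration_q05,overall,2016,112
duration_q05,overall,2017,83
duration_q05,overall,2018,114
duration_q05,overall,2019,88
duration_q05,overall,2020,81
duration_q05,overall,2021,66
duration_q05,overall,mean,93
total_growth,control,2010,1572
total_growth,control,2011,1672
total_growth,control,2012,1260
total_growth,control,2013,679
total_growth,control,2014,547
total_growth,control,2015,685
total_growth,control,2016,896
total_growth,control,2017,1292
total_growth,control,2018,1107
total_growth,control,2019,1055
total_growth,control,2020,1102
total_growth,control,2021,1065
total_growth,control,mean,1115
total_growth,heated,2010,1018
total_growth,heated,2011,1031
total_growth,heated,2012,1079
total_growth,heated,2013,824
total_growth,heated,2014,818
total_growth,heated,2015,1301
total_growth,heated,2016,1513
total_growth,heated,2017,1957
total_growth,heated,2018,1409
total_growth,heated,2019,1504
total_growth,heated,2020,1547
total_growth,heated,2021,1090
total_growth,heated,mean,1216
total_growth,overall,2010,1295
total_growth,overall,2011,1322
total_growth,overall,2012,1178
total_growth,overall,2013,741
total_growth,overall,2014,663
total_growth,overall,2015,949
total_growth,overall,2016,1160
total_growth,overall,2017,1577
total_growth,overall,2018,1228
total_growth,overall,2019,1248
total_growth,overall,2020,1293
total_growth,overall,2021,1073
total_growth,overall,mean,1160
rate,control,2010,15.4
rate,control,2011,21.6
rate,control,2012,16.6
rate,control,2013,7.4
rate,control,2014,4.3
rate,control,2015,8.0
rate,control,2016,8.5
rate,control,2017,15.1
rate,control,2018,7.9
rate,control,2019,11.3
rate,control,2020,13.9
rate,control,2021,15.8
rate,control,mean,12.7
rate,heated,2010,11.4
rate,heated,2011,14.9
rate,heated,2012,12.7
rate,heated,2013,8.9
rate,heated,2014,8.1
rate,heated,2015,16.4
rate,heated,2016,13.9
rate,heated,2017,26.9
rate,heated,2018,17.6
rate,heated,2019,18.7
rate,heated,2020,20.4
rate,heated,2021,17.9
rate,heated,mean,15.0
rate,overall,2010,13.4
rate,overall,2011,17.9
rate,overall,2012,14.8
rate,overall,2013,8.0
rate,overall,2014,5.9
rate,overall,2015,11.6
rate,overall,2016,10.8
rate,overall,2017,20.2
rate,overall,2018,11.8
rate,overall,2019,14.4
rate,overall,2020,16.7
rate,overall,2021,16.5
rate,overall,mean,13.7
cessation_q10,overall,mean,222
cessation_q20,overall,mean,201
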