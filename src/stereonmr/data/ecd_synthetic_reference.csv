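wavelength_nm,delta_epsilon
180.0,0.00000
180.5,0.00000
181.0,0.00001
181.5,0.00001
182.0,0.00002
182.5,0.00004
183.0,0.00007
183.5,0.00011
184.0,0.00018
184.5,0.00029
185.0,0.00046
185.5,0.00072
186.0,0.00113
186.5,0.00174
187.0,0.00267
187.5,0.00404
188.0,0.00605
188.5,0.00898
189.0,0.01320
189.5,0.01921
190.0,0.02767
190.5,0.03946
191.0,0.05572
191.5,0.07789
192.0,0.10781
192.5,0.14772
193.0,0.20041
193.5,0.26917
194.0,0.35793
194.5,0.47123
195.0,0.61422
195.5,0.79262
196.0,1.01267
196.5,1.28094
197.0,1.60415
197.5,1.98892
198.0,2.44145
198.5,2.96712
199.0,3.57009
199.5,4.25286
200.0,5.01579
200.5,5.85673
201.0,6.77061
201.5,7.74921
202.0,8.78101
202.5,9.85118
203.0,10.94181
203.5,12.03225
204.0,13.09971
204.5,14.11995
205.0,15.06822
205.5,15.92015
206.0,16.65286
206.5,17.24594
207.0,17.68238
207.5,17.94939
208.0,18.03901
208.5,17.94850
209.0,17.68045
209.5,17.24266
210.0,16.64773
210.5,15.91239
211.0,15.05673
211.5,14.10319
212.0,13.07553
212.5,11.99774
213.0,10.89307
213.5,9.78305
214.0,8.68671
214.5,7.62000
215.0,6.59531
215.5,5.62128
216.0,4.70270
216.5,3.84066
217.0,3.03282
217.5,2.27379
218.0,1.55564
218.5,0.86845
219.0,0.20096
219.5,-0.45882
220.0,-1.12292
220.5,-1.80278
221.0,-2.50863
221.5,-3.24884
222.0,-4.02950
222.5,-4.85384
223.0,-5.72200
223.5,-6.63069
224.0,-7.57314
224.5,-8.53916
225.0,-9.51533
225.5,-10.48543
226.0,-11.43096
226.5,-12.33187
227.0,-13.16736
227.5,-13.91682
228.0,-14.56072
228.5,-15.08160
229.0,-15.46487
229.5,-15.69955
230.0,-15.77887
230.5,-15.70057
231.0,-15.46708
231.5,-15.08535
232.0,-14.56660
232.5,-13.92569
233.0,-13.18050
233.5,-12.35104
234.0,-11.45861
234.5,-10.52488
235.0,-9.57105
235.5,-8.61705
236.0,-7.68095
236.5,-6.77841
237.0,-5.92241
237.5,-5.12302
238.0,-4.38743
238.5,-3.72007
239.0,-3.12284
239.5,-2.59541
240.0,-2.13559
240.5,-1.73975
241.0,-1.40318
241.5,-1.12046
242.0,-0.88581
242.5,-0.69332
243.0,-0.53727
243.5,-0.41220
244.0,-0.31309
244.5,-0.23545
245.0,-0.17530
245.5,-0.12922
246.0,-0.09430
246.5,-0.06814
247.0,-0.04874
247.5,-0.03452
248.0,-0.02420
248.5,-0.01680
249.0,-0.01155
249.5,-0.00786
250.0,-0.00529
250.5,-0.00353
251.0,-0.00233
251.5,-0.00152
252.0,-0.00099
252.5,-0.00063
253.0,-0.00040
253.5,-0.00025
254.0,-0.00016
254.5,-0.00010
255.0,-0.00006
255.5,-0.00004
256.0,-0.00002
256.5,-0.00001
257.0,-0.00001
257.5,-0.00000
258.0,-0.00000
258.5,-0.00000
259.0,-0.00000
259.5,-0.00000
260.0,-0.00000
260.5,-0.00000
261.0,-0.00000
261.5,-0.00000
262.0,-0.00000
262.5,-0.00000
263.0,-0.00000
263.5,-0.00000
264.0,-0.00000
264.5,-0.00000
265.0,-0.00000
265.5,-0.00000
266.0,-0.00000
266.5,-0.00000
267.0,-0.00000
267.5,-0.00000
268.0,-0.00000
268.5,-0.00000
269.0,-0.00000
269.5,-0.00000
270.0,-0.00000
270.5,-0.00000
271.0,-0.00000
271.5,-0.00000
272.0,-0.00000
272.5,-0.00000
273.0,-0.00000
273.5,-0.00000
274.0,-0.00000
274.5,-0.00000
275.0,-0.00000
275.5,-0.00000
276.0,-0.00000
276.5,-0.00000
277.0,-0.00000
277.5,-0.00000
278.0,-0.00000
278.5,-0.00000
279.0,-0.00000
279.5,-0.00000
280.0,-0.00000
280.5,-0.00000
281.0,-0.00000
281.5,-0.00000
282.0,-0.00000
282.5,-0.00000
283.0,-0.00000
283.5,-0.00000
284.0,-0.00000
284.5,-0.00000
285.0,-0.00000
285.5,-0.00000
286.0,-0.00000
286.5,-0.00000
287.0,-0.00000
287.5,-0.00000
288.0,-0.00000
288.5,-0.00000
289.0,-0.00000
289.5,-0.00000
290.0,-0.00000
290.5,-0.00000
291.0,-0.00000
291.5,-0.00000
292.0,-0.00000
292.5,-0.00000
293.0,-0.00000
293.5,-0.00000
294.0,-0.00000
294.5,-0.00000
295.0,-0.00000
295.5,-0.00000
296.0,-0.00000
296.5,-0.00000
297.0,-0.00000
297.5,-0.00000
298.0,-0.00000
298.5,-0.00000
299.0,-0.00000
299.5,-0.00000
300.0,-0.00000
300.5,-0.00000
301.0,-0.00000
301.5,-0.00000
302.0,-0.00000
302.5,-0.00000
303.0,-0.00000
303.5,-0.00000
304.0,-0.00000
304.5,-0.00000
305.0,-0.00000
305.5,-0.00000
306.0,-0.00000
306.5,-0.00000
307.0,-0.00000
307.5,-0.00000
308.0,-0.00000
308.5,-0.00000
309.0,-0.00000
309.5,-0.00000
310.0,-0.00000
310.5,-0.00000
311.0,-0.00000
311.5,-0.00000
312.0,-0.00000
312.5,-0.00000
313.0,-0.00000
313.5,-0.00000
314.0,-0.00000
314.5,-0.00000
315.0,-0.00000
315.5,-0.00000
316.0,-0.00000
316.5,-0.00000
317.0,-0.00000
317.5,-0.00000
318.0,-0.00000
318.5,-0.00000
319.0,-0.00000
319.5,-0.00000
320.0,-0.00000
320.5,-0.00000
321.0,-0.00000
321.5,-0.00000
322.0,-0.00000
322.5,-0.00000
323.0,-0.00000
323.5,-0.00000
324.0,-0.00000
324.5,-0.00000
325.0,-0.00000
325.5,-0.00000
326.0,-0.00000
326.5,-0.00000
327.0,-0.00000
327.5,-0.00000
328.0,-0.00000
328.5,-0.00000
329.0,-0.00000
329.5,-0.00000
330.0,-0.00000
330.5,-0.00000
331.0,-0.00000
331.5,-0.00000
332.0,-0.00000
332.5,-0.00000
333.0,-0.00000
333.5,-0.00000
334.0,-0.00000
334.5,-0.00000
335.0,-0.00000
335.5,-0.00000
336.0,-0.00000
336.5,-0.00000
337.0,-0.00000
337.5,-0.00000
338.0,-0.00000
338.5,-0.00000
339.0,-0.00000
339.5,-0.00000
340.0,-0.00000
340.5,-0.00000
341.0,-0.00000
341.5,-0.00000
342.0,-0.00000
342.5,-0.00000
343.0,-0.00000
343.5,-0.00000
344.0,-0.00000
344.5,-0.00000
345.0,-0.00000
345.5,-0.00000
346.0,-0.00000
346.5,-0.00000
347.0,-0.00000
347.5,-0.00000
348.0,-0.00000
348.5,-0.00000
349.0,-0.00000
349.5,-0.00000
350.0,-0.00000
350.5,-0.00000
351.0,-0.00000
351.5,-0.00000
352.0,-0.00000
352.5,-0.00000
353.0,-0.00000
353.5,-0.00000
354.0,-0.00000
354.5,-0.00000
355.0,-0.00000
355.5,-0.00000
356.0,-0.00000
356.5,-0.00000
357.0,-0.00000
357.5,-0.00000
358.0,-0.00000
358.5,-0.00000
359.0,-0.00000
359.5,-0.00000
360.0,-0.00000
360.5,-0.00000
361.0,-0.00000
361.5,-0.00000
362.0,-0.00000
362.5,-0.00000
363.0,-0.00000
363.5,-0.00000
364.0,-0.00000
364.5,-0.00000
365.0,-0.00000
365.5,-0.00000
366.0,-0.00000
366.5,-0.00000
367.0,-0.00000
367.5,-0.00000
368.0,-0.00000
368.5,-0.00000
369.0,-0.00000
369.5,-0.00000
370.0,-0.00000
370.5,-0.00000
371.0,-0.00000
371.5,-0.00000
372.0,-0.00000
372.5,-0.00000
373.0,-0.00000
373.5,-0.00000
374.0,-0.00000
374.5,-0.00000
375.0,-0.00000
375.5,-0.00000
376.0,-0.00000
376.5,-0.00000
377.0,-0.00000
377.5,-0.00000
378.0,-0.00000
378.5,-0.00000
379.0,-0.00000
379.5,-0.00000
380.0,-0.00000
380.5,-0.00000
381.0,-0.00000
381.5,-0.00000
382.0,-0.00000
382.5,-0.00000
383.0,-0.00000
383.5,-0.00000
384.0,-0.00000
384.5,-0.00000
385.0,-0.00000
385.5,-0.00000
386.0,-0.00000
386.5,-0.00000
387.0,-0.00000
387.5,-0.00000
388.0,-0.00000
388.5,-0.00000
389.0,-0.00000
389.5,-0.00000
390.0,-0.00000
390.5,-0.00000
391.0,-0.00000
391.5,-0.00000
392.0,-0.00000
392.5,-0.00000
393.0,-0.00000
393.5,-0.00000
394.0,-0.00000
394.5,-0.00000
395.0,-0.00000
395.5,-0.00000
396.0,-0.00000
396.5,-0.00000
397.0,-0.00000
397.5,-0.00000
398.0,-0.00000
398.5,-0.00000
399.0,-0.00000
399.5,-0.00000
400.0,-0.00000
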