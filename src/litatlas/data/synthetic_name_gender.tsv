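name	year	prop_female
Leslie	1930	0.100
Leslie	1940	0.249
Leslie	1950	0.398
Leslie	1960	0.547
Leslie	1970	0.696
Leslie	1980	0.845
Leslie	1990	0.920
Leslie	2000	0.920
Leslie	2010	0.920
Leslie	2012	0.920
Mary	1930	0.996
Mary	1940	0.996
Mary	1950	0.996
Mary	1960	0.996
Mary	1970	0.996
Mary	1980	0.996
Mary	1990	0.996
Mary	2000	0.996
Mary	2010	0.996
Mary	2012	0.996
Linda	1930	0.994
Linda	1940	0.994
Linda	1950	0.994
Linda	1960	0.994
Linda	1970	0.994
Linda	1980	0.994
Linda	1990	0.994
Linda	2000	0.994
Linda	2010	0.994
Linda	2012	0.994
Patricia	1930	0.993
Patricia	1940	0.993
Patricia	1950	0.993
Patricia	1960	0.993
Patricia	1970	0.993
Patricia	1980	0.993
Patricia	1990	0.993
Patricia	2000	0.993
Patricia	2010	0.993
Patricia	2012	0.993
Barbara	1930	0.995
Barbara	1940	0.995
Barbara	1950	0.995
Barbara	1960	0.995
Barbara	1970	0.995
Barbara	1980	0.995
Barbara	1990	0.995
Barbara	2000	0.995
Barbara	2010	0.995
Barbara	2012	0.995
Susan	1930	0.994
Susan	1940	0.994
Susan	1950	0.994
Susan	1960	0.994
Susan	1970	0.994
Susan	1980	0.994
Susan	1990	0.994
Susan	2000	0.994
Susan	2010	0.994
Susan	2012	0.994
Jennifer	1930	0.996
Jennifer	1940	0.996
Jennifer	1950	0.996
Jennifer	1960	0.996
Jennifer	1970	0.996
Jennifer	1980	0.996
Jennifer	1990	0.996
Jennifer	2000	0.996
Jennifer	2010	0.996
Jennifer	2012	0.996
Karen	1930	0.993
Karen	1940	0.993
Karen	1950	0.993
Karen	1960	0.993
Karen	1970	0.993
Karen	1980	0.993
Karen	1990	0.993
Karen	2000	0.993
Karen	2010	0.993
Karen	2012	0.993
Elizabeth	1930	0.995
Elizabeth	1940	0.995
Elizabeth	1950	0.995
Elizabeth	1960	0.995
Elizabeth	1970	0.995
Elizabeth	1980	0.995
Elizabeth	1990	0.995
Elizabeth	2000	0.995
Elizabeth	2010	0.995
Elizabeth	2012	0.995
Maria	1930	0.992
Maria	1940	0.992
Maria	1950	0.992
Maria	1960	0.992
Maria	1970	0.992
Maria	1980	0.992
Maria	1990	0.992
Maria	2000	0.992
Maria	2010	0.992
Maria	2012	0.992
Eva	1930	0.985
Eva	1940	0.985
Eva	1950	0.985
Eva	1960	0.985
Eva	1970	0.985
Eva	1980	0.985
Eva	1990	0.985
Eva	2000	0.985
Eva	2010	0.985
Eva	2012	0.985
Nancy	1930	0.991
Nancy	1940	0.991
Nancy	1950	0.991
Nancy	1960	0.991
Nancy	1970	0.991
Nancy	1980	0.991
Nancy	1990	0.991
Nancy	2000	0.991
Nancy	2010	0.991
Nancy	2012	0.991
Emily	1930	0.994
Emily	1940	0.994
Emily	1950	0.994
Emily	1960	0.994
Emily	1970	0.994
Emily	1980	0.994
Emily	1990	0.994
Emily	2000	0.994
Emily	2010	0.994
Emily	2012	0.994
Sarah	1930	0.995
Sarah	1940	0.995
Sarah	1950	0.995
Sarah	1960	0.995
Sarah	1970	0.995
Sarah	1980	0.995
Sarah	1990	0.995
Sarah	2000	0.995
Sarah	2010	0.995
Sarah	2012	0.995
John	1930	0.004
John	1940	0.004
John	1950	0.004
John	1960	0.004
John	1970	0.004
John	1980	0.004
John	1990	0.004
John	2000	0.004
John	2010	0.004
John	2012	0.004
James	1930	0.005
James	1940	0.005
James	1950	0.005
James	1960	0.005
James	1970	0.005
James	1980	0.005
James	1990	0.005
James	2000	0.005
James	2010	0.005
James	2012	0.005
Robert	1930	0.004
Robert	1940	0.004
Robert	1950	0.004
Robert	1960	0.004
Robert	1970	0.004
Robert	1980	0.004
Robert	1990	0.004
Robert	2000	0.004
Robert	2010	0.004
Robert	2012	0.004
Michael	1930	0.006
Michael	1940	0.006
Michael	1950	0.006
Michael	1960	0.006
Michael	1970	0.006
Michael	1980	0.006
Michael	1990	0.006
Michael	2000	0.006
Michael	2010	0.006
Michael	2012	0.006
David	1930	0.005
David	1940	0.005
David	1950	0.005
David	1960	0.005
David	1970	0.005
David	1980	0.005
David	1990	0.005
David	2000	0.005
David	2010	0.005
David	2012	0.005
Richard	1930	0.004
Richard	1940	0.004
Richard	1950	0.004
Richard	1960	0.004
Richard	1970	0.004
Richard	1980	0.004
Richard	1990	0.004
Richard	2000	0.004
Richard	2010	0.004
Richard	2012	0.004
Thomas	1930	0.005
Thomas	1940	0.005
Thomas	1950	0.005
Thomas	1960	0.005
Thomas	1970	0.005
Thomas	1980	0.005
Thomas	1990	0.005
Thomas	2000	0.005
Thomas	2010	0.005
Thomas	2012	0.005
Jose	1930	0.007
Jose	1940	0.007
Jose	1950	0.007
Jose	1960	0.007
Jose	1970	0.007
Jose	1980	0.007
Jose	1990	0.007
Jose	2000	0.007
Jose	2010	0.007
Jose	2012	0.007
William	1930	0.004
William	1940	0.004
William	1950	0.004
William	1960	0.004
William	1970	0.004
William	1980	0.004
William	1990	0.004
William	2000	0.004
William	2010	0.004
William	2012	0.004
Charles	1930	0.005
Charles	1940	0.005
Charles	1950	0.005
Charles	1960	0.005
Charles	1970	0.005
Charles	1980	0.005
Charles	1990	0.005
Charles	2000	0.005
Charles	2010	0.005
Charles	2012	0.005
Daniel	1930	0.006
Daniel	1940	0.006
Daniel	1950	0.006
Daniel	1960	0.006
Daniel	1970	0.006
Daniel	1980	0.006
Daniel	1990	0.006
Daniel	2000	0.006
Daniel	2010	0.006
Daniel	2012	0.006
Alex	1930	0.120
Alex	1940	0.140
Alex	1950	0.159
Alex	1960	0.179
Alex	1970	0.198
Alex	1980	0.218
Alex	1990	0.237
Alex	2000	0.257
Alex	2010	0.276
Alex	2012	0.280
Jamie	1930	0.350
Jamie	1940	0.383
Jamie	1950	0.416
Jamie	1960	0.449
Jamie	1970	0.482
Jamie	1980	0.515
Jamie	1990	0.548
Jamie	2000	0.580
Jamie	2010	0.613
Jamie	2012	0.620
Morgan	1930	0.200
Morgan	1940	0.262
Morgan	1950	0.324
Morgan	1960	0.387
Morgan	1970	0.449
Morgan	1980	0.511
Morgan	1990	0.573
Morgan	2000	0.635
Morgan	2010	0.698
Morgan	2012	0.710
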